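"""Per-bird-day diurnal mass trajectory fitting and dawn/dusk estimation.

Stable masses from one bird on one day are modelled as a polynomial in time
of day. Fitting follows a two-pass rule: an initial cubic is fitted by
ordinary least squares, points falling more than ``residual_cut_g`` (10 g)
from it are discarded as biologically implausible, and the cubic is refitted
once to the retained points. A bird-day is only fitted if at least
``min_points`` (10) masses are available, re-checked after the exclusion
pass. Mass at a specific time (dawn 0800, noon 1200, dusk 1600) is read off
the refitted polynomial, but only when a retained mass lies within
``guard_h`` (1 h) of the requested time, so estimates never extrapolate far
beyond the data. Daily gain is dusk - dawn within a day; nightly loss is the
previous day's dusk minus today's dawn.

Polynomial degree (1, 2 or 3) can be compared per bird-day by AIC; the
decelerating, possibly twice-inflected shape of avian diurnal mass gain
generally favours the cubic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DailyTrajectoryFit",
    "fit_daily_trajectory",
    "fit_bird_days",
    "select_polynomial_degree",
    "estimate_mass_at",
    "hourly_estimates",
    "summarise_bird_days",
]

DAWN_H = 8.0
NOON_H = 12.0
DUSK_H = 16.0
SESSION_END_H = 17.25
#: Polynomial time covariate is centred at dawn to reduce collinearity.
TIME_ORIGIN_H = 8.0

_TINY_RSS = 1e-30


@dataclass
class DailyTrajectoryFit:
    """One bird-day's refitted polynomial trajectory.

    ``coeffs`` are ascending-power coefficients over centred time
    ``u = t_h - 8``. ``t_retained_h`` holds the time points that survived the
    residual exclusion; the dawn/dusk guard rule consults them.
    """

    bird_id: str
    day: int
    degree: int
    coeffs: np.ndarray
    n_used: int
    n_excluded_residual: int
    r_squared: float
    rss: float
    aic: float
    t_retained_h: np.ndarray
    mass_retained_g: np.ndarray

    def predict(self, t_h: float | np.ndarray) -> float | np.ndarray:
        u = np.asarray(t_h, dtype=float) - TIME_ORIGIN_H
        out = np.polynomial.polynomial.polyval(u, self.coeffs)
        return float(out) if np.isscalar(t_h) else out


def _polyfit(t_h: np.ndarray, mass: np.ndarray,
             degree: int) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS polynomial fit on centred time; returns (coeffs, fitted, rss)."""
    u = t_h - TIME_ORIGIN_H
    X = np.vander(u, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(X, mass, rcond=None)
    fitted = X @ coeffs
    rss = float(((mass - fitted) ** 2).sum())
    return coeffs, fitted, rss


def _aic_gaussian(n: int, rss: float, degree: int) -> float:
    # Gaussian profile likelihood; k counts the polynomial coefficients plus
    # the error variance.
    k = degree + 2
    return n * np.log(max(rss, _TINY_RSS) / n) + 2 * k


def fit_daily_trajectory(times_h: np.ndarray, masses_g: np.ndarray, *,
                         bird_id: str = "", day: int = 0,
                         degree: int = 3, min_points: int = 10,
                         residual_cut_g: float = 10.0,
                         ) -> DailyTrajectoryFit | None:
    """Two-pass polynomial fit to one bird-day's stable masses.

    Returns ``None`` when fewer than ``min_points`` masses are available
    (before or after the exclusion pass) or when the design is degenerate
    (all masses at a single time point). Exactly one residual-exclusion pass
    is applied: points with |residual| > ``residual_cut_g`` from the pass-1
    fit are dropped and the polynomial refitted once.
    """
    t = np.asarray(times_h, dtype=float)
    m = np.asarray(masses_g, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ValueError("times_h and masses_g must be equal-length 1-d arrays")
    if len(t) < min_points:
        return None
    if np.ptp(t) == 0.0:
        return None  # degenerate design: no time variation
    _, fitted1, _ = _polyfit(t, m, degree)
    keep = np.abs(m - fitted1) <= residual_cut_g
    if keep.sum() < min_points:
        return None
    t2, m2 = t[keep], m[keep]
    if np.ptp(t2) == 0.0:
        return None
    coeffs, fitted2, rss = _polyfit(t2, m2, degree)
    tss = float(((m2 - m2.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    return DailyTrajectoryFit(
        bird_id=bird_id, day=day, degree=degree,
        coeffs=np.asarray(coeffs, dtype=float),
        n_used=int(keep.sum()),
        n_excluded_residual=int((~keep).sum()),
        r_squared=float(r2), rss=rss,
        aic=_aic_gaussian(int(keep.sum()), rss, degree),
        t_retained_h=t2, mass_retained_g=m2,
    )


def select_polynomial_degree(times_h: np.ndarray, masses_g: np.ndarray, *,
                             degrees: tuple[int, ...] = (1, 2, 3),
                             ) -> tuple[int, dict[int, float]]:
    """Choose the polynomial degree with the lowest Gaussian AIC.

    AIC = n ln(RSS/n) + 2k with k = degree + 2 (coefficients plus the error
    variance). Ties break toward the lower degree.
    """
    t = np.asarray(times_h, dtype=float)
    m = np.asarray(masses_g, dtype=float)
    if len(t) < 10:
        raise ValueError("degree selection requires at least 10 masses")
    aics: dict[int, float] = {}
    for d in sorted(degrees):
        _, _, rss = _polyfit(t, m, d)
        aics[d] = _aic_gaussian(len(t), rss, d)
    best = min(aics, key=lambda d: (aics[d], d))
    return best, aics


def estimate_mass_at(fit: DailyTrajectoryFit, time_h: float, *,
                     guard_h: float = 1.0) -> float | None:
    """Polynomial mass estimate at ``time_h``, guarded against extrapolation.

    Returns ``None`` unless some retained mass lies within ``guard_h`` hours
    of ``time_h``. Times outside the session window (0800 to 1715) are
    rejected.
    """
    if not (DAWN_H <= time_h <= SESSION_END_H):
        raise ValueError(f"time {time_h} h outside the session window "
                         f"[{DAWN_H}, {SESSION_END_H}]")
    if not np.any(np.abs(fit.t_retained_h - time_h) <= guard_h):
        return None
    return float(fit.predict(time_h))


def fit_bird_days(stable_masses: pd.DataFrame, *, degree: int = 3,
                  min_points: int = 10, residual_cut_g: float = 10.0,
                  ) -> dict[tuple[str, int], DailyTrajectoryFit]:
    """Fit every (bird, day) group in an attributed stable-mass table.

    ``stable_masses`` needs columns ``bird_id``, ``day``, ``t`` (seconds
    since midnight) and ``mass_g``. Bird-days that cannot be fitted (too few
    masses) are simply absent from the result.
    """
    fits: dict[tuple[str, int], DailyTrajectoryFit] = {}
    for (bird, day), grp in stable_masses.groupby(["bird_id", "day"],
                                                  sort=True):
        fit = fit_daily_trajectory(
            grp["t"].to_numpy() / 3600.0, grp["mass_g"].to_numpy(),
            bird_id=str(bird), day=int(day), degree=degree,
            min_points=min_points, residual_cut_g=residual_cut_g)
        if fit is not None:
            fits[(str(bird), int(day))] = fit
    return fits


def hourly_estimates(fits: dict[tuple[str, int], DailyTrajectoryFit], *,
                     guard_h: float = 1.0) -> pd.DataFrame:
    """Guarded fitted masses on integer hours 0800-1600, tidy long format."""
    rows = []
    for (bird, day), fit in sorted(fits.items()):
        for h in range(int(DAWN_H), int(DUSK_H) + 1):
            rows.append((bird, day, h,
                         estimate_mass_at(fit, float(h), guard_h=guard_h)))
    return pd.DataFrame(rows, columns=["bird_id", "day", "hour",
                                       "fitted_mass_g"])


def summarise_bird_days(fits: dict[tuple[str, int], DailyTrajectoryFit],
                        reinforcements: pd.DataFrame | None = None, *,
                        guard_h: float = 1.0) -> pd.DataFrame:
    """Per bird-day dawn/noon/dusk masses, daily gain, and nightly loss.

    Gain is defined only when both dawn and dusk estimates pass the guard
    rule; loss on day d only when day d-1's dusk and day d's dawn are both
    present. ``reinforcements`` (columns bird_id, day, reinforcements) is
    merged in when given; bird-days without fits appear with missing masses
    so their effort data are not lost.
    """
    rows = []
    for (bird, day), fit in sorted(fits.items()):
        dawn = estimate_mass_at(fit, DAWN_H, guard_h=guard_h)
        noon = estimate_mass_at(fit, NOON_H, guard_h=guard_h)
        dusk = estimate_mass_at(fit, DUSK_H, guard_h=guard_h)
        rows.append((bird, day, dawn, noon, dusk))
    out = pd.DataFrame(rows, columns=["bird_id", "day", "dawn_mass_g",
                                      "noon_mass_g", "dusk_mass_g"])
    out["daily_gain_g"] = out["dusk_mass_g"] - out["dawn_mass_g"]
    prev = out[["bird_id", "day", "dusk_mass_g"]].copy()
    prev["day"] += 1
    prev = prev.rename(columns={"dusk_mass_g": "_prev_dusk"})
    out = out.merge(prev, on=["bird_id", "day"], how="left")
    out["nightly_loss_g"] = out["_prev_dusk"] - out["dawn_mass_g"]
    out = out.drop(columns="_prev_dusk")
    if reinforcements is not None:
        out = out.merge(reinforcements[["bird_id", "day", "reinforcements"]],
                        on=["bird_id", "day"], how="outer")
        out = out.sort_values(["bird_id", "day"]).reset_index(drop=True)
    return out
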