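"""Streaming stable-mass detection and RFID attribution.

A perch balance sampled at 6 Hz produces a noisy stream that mixes true bird
masses, readings from badly perched birds, and near-zero baseline readings
between visits. A *stable mass* is recorded at the first run of
``window_n`` consecutive readings all above ``min_mass_g`` whose spread
(max - min) is at most ``range_g``; once recorded, detection is locked out
until the balance registers a reading below ``reset_below_g``, indicating
that the bird has left the perch. Each stable mass is then attributed to the
bird whose RFID chip was read most recently on that station, and grossly
implausible masses (> 120 g, above anything a starling can weigh) are
removed before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "AttributionResult",
    "attribute_masses",
    "detect_stable_masses",
    "detect_stable_masses_stream",
    "filter_gross_outliers",
]


def detect_stable_masses_stream(t: np.ndarray, mass_g: np.ndarray, *,
                                min_mass_g: float = 50.0,
                                range_g: float = 5.0,
                                window_n: int = 5,
                                reset_below_g: float = 10.0,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Detect stable-mass events in one station's time-ordered stream.

    Returns ``(event_t, event_mass)`` where each event's time is the last
    reading of its qualifying window and its mass is the window mean. The
    first qualifying window is emitted; later overlapping windows in the same
    visit are suppressed by the lockout, which releases only after a reading
    below ``reset_below_g``.

    Raises ``ValueError`` if ``t`` is not non-decreasing.
    """
    t = np.asarray(t, dtype=float)
    m = np.asarray(mass_g, dtype=float)
    if t.ndim != 1 or t.shape != m.shape:
        raise ValueError("t and mass_g must be equal-length 1-d arrays")
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError("readings must be time-ordered")
    n = len(m)
    if n < window_n:
        return np.empty(0), np.empty(0)

    win = sliding_window_view(m, window_n)
    valid = ((win > min_mass_g).all(axis=1)
             & (win.max(axis=1) - win.min(axis=1) <= range_g))
    valid_starts = np.flatnonzero(valid)
    reset_idx = np.flatnonzero(m < reset_below_g)

    ev_t, ev_m = [], []
    pos = 0  # earliest admissible window start
    vp = 0   # pointer into valid_starts
    while True:
        vp = np.searchsorted(valid_starts, pos, side="left")
        if vp >= len(valid_starts):
            break
        i = int(valid_starts[vp])
        j = i + window_n - 1
        ev_t.append(t[j])
        ev_m.append(m[i:i + window_n].mean())
        # locked out until a reading < reset_below_g strictly after the window
        rp = np.searchsorted(reset_idx, j, side="right")
        if rp >= len(reset_idx):
            break
        pos = int(reset_idx[rp]) + 1
    return np.asarray(ev_t), np.asarray(ev_m)


def detect_stable_masses(readings: pd.DataFrame, *,
                         min_mass_g: float = 50.0,
                         range_g: float = 5.0,
                         window_n: int = 5,
                         reset_below_g: float = 10.0) -> pd.DataFrame:
    """Run the stable-mass detector over a balance log.

    ``readings`` must have columns ``t`` and ``mass_g``; optional
    ``station_id`` and ``day`` columns partition the stream (detection state
    never carries across stations or days). Returns a frame with columns
    ``station_id``, ``day`` (where present), ``t``, ``mass_g``, time-ordered
    within each partition.
    """
    keys = [c for c in ("station_id", "day") if c in readings.columns]
    out = []
    groups = readings.groupby(keys, sort=True) if keys else [((), readings)]
    for key, grp in groups:
        ev_t, ev_m = detect_stable_masses_stream(
            grp["t"].to_numpy(), grp["mass_g"].to_numpy(),
            min_mass_g=min_mass_g, range_g=range_g, window_n=window_n,
            reset_below_g=reset_below_g)
        part = pd.DataFrame({"t": ev_t, "mass_g": ev_m})
        if keys:
            if not isinstance(key, tuple):
                key = (key,)
            for c, v in zip(keys, key):
                part[c] = v
        out.append(part)
    if not out:
        return pd.DataFrame(columns=keys + ["t", "mass_g"])
    res = pd.concat(out, ignore_index=True)
    return res[keys + ["t", "mass_g"]]


@dataclass
class AttributionResult:
    """Bird-attributed stable masses plus attribution QC counts."""

    masses: pd.DataFrame      # bird_id, station_id, day, t, mass_g
    n_attributed: int
    n_dropped_no_read: int    # no RFID read within staleness window
    n_dropped_unknown_chip: int


def attribute_masses(events: pd.DataFrame, rfid_reads: pd.DataFrame,
                     ring_map: pd.DataFrame | dict, *,
                     staleness_s: float = 5.0) -> AttributionResult:
    """Assign each stable-mass event to the bird last read on that station.

    An event at time ``t`` is attributed to the bird whose chip was read most
    recently on the same station (and day, if present) no more than
    ``staleness_s`` seconds before ``t``. Events with no qualifying read are
    dropped and counted; reads whose chip is absent from the ring map trigger
    a warning and are ignored (a bird's two chips both map to its id, so
    either read attributes correctly).
    """
    if isinstance(ring_map, dict):
        ring = pd.DataFrame(ring_map.items(), columns=["chip_id", "bird_id"])
    else:
        ring = ring_map[["chip_id", "bird_id"]]
    known = rfid_reads["chip_id"].isin(set(ring["chip_id"]))
    n_unknown = int((~known).sum())
    if n_unknown:
        warnings.warn(f"{n_unknown} RFID reads with chips absent from the "
                      "ring map were ignored", stacklevel=2)
    reads = rfid_reads[known].merge(ring, on="chip_id")

    keys = [c for c in ("station_id", "day") if c in events.columns]
    ev = events.reset_index(drop=True).reset_index(names="_ev")
    ev_sorted = ev.sort_values(["t", "_ev"], kind="stable")
    reads_sorted = reads.sort_values("t", kind="stable")
    merged = pd.merge_asof(ev_sorted, reads_sorted[keys + ["t", "bird_id"]],
                           on="t", by=keys if keys else None,
                           direction="backward", tolerance=staleness_s)
    merged = merged.sort_values("_ev", kind="stable")
    ok = merged["bird_id"].notna()
    masses = merged.loc[ok, ["bird_id"] + keys + ["t", "mass_g"]] \
        .reset_index(drop=True)
    return AttributionResult(
        masses=masses,
        n_attributed=int(ok.sum()),
        n_dropped_no_read=int((~ok).sum()),
        n_dropped_unknown_chip=n_unknown,
    )


def filter_gross_outliers(masses: pd.DataFrame, *,
                          max_g: float = 120.0,
                          column: str = "mass_g",
                          ) -> tuple[pd.DataFrame, int]:
    """Remove masses above ``max_g`` (measurement errors); report the count.

    Returns ``(retained, n_excluded)`` where retained rows satisfy
    ``mass_g <= max_g``.
    """
    keep = masses[column] <= max_g
    return masses[keep].reset_index(drop=True), int((~keep).sum())
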