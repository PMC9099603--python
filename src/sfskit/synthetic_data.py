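"""Synthetic social-foraging-system event logs with known ground truth.

Generates the raw data streams a bank of SFS stations would write during a
closed-economy study — 6 Hz balance readings, RFID perch reads, key-peck /
reinforcement events, and a daily hopper/spill-tray ledger — from latent
per-bird parameters (diurnal mass trajectory, visit process, balance noise).
Because the generator records its own ground truth, every downstream stage
(stable-mass detection, attribution, trajectory fitting, effort summaries,
mixed models) can be tested by parameter recovery rather than by eye.

Conventions
-----------
* Clock times are seconds since local midnight; trajectory time is hours.
* Lights (and the operant session) run 0800-1715; dawn is defined as 0800
  and dusk as 1600 for mass estimation.
* Each bird wears two RFID chips (redundancy against read failure); both map
  to the same bird in the ring map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BirdProfile",
    "ScheduleConfig",
    "SimConfig",
    "SimBundle",
    "autoshaping_schedule",
    "conditional_training_schedule",
    "continuous_foraging_schedule",
    "make_bird_profiles",
    "simulate_experiment",
    "simulate_training_sessions",
]

#: Lights-on / session start (0800) in seconds since midnight.
LIGHTS_ON_S = 8 * 3600
#: Lights-off / session end (1715) in seconds since midnight.
LIGHTS_OFF_S = 17 * 3600 + 15 * 60

DAWN_H = 8.0
DUSK_H = 16.0

# Observed cohort ranges used as sampling bounds for latent parameters:
# dawn mass 71.1-91.4 g, daily gain 3.6-8.3 g, reinforcements/day 129-568.
DAWN_MASS_RANGE_G = (71.1, 91.4)
DAILY_GAIN_RANGE_G = (3.6, 8.3)
REINFORCEMENTS_RANGE = (129.0, 568.0)


@dataclass(frozen=True)
class ScheduleConfig:
    """Operant schedule parameters for one phase of the study.

    ``mode`` is one of ``"autoshaping"`` (key light predicts unconditional
    hopper raising), ``"conditional"`` (trial-structured, food contingent on
    a key peck), or ``"continuous"`` (free-running fixed-ratio closed
    economy). ``assumed_latency_s`` is the peck latency assumed when
    computing the theoretical daily reinforcement capacity of one station.
    """

    mode: str = "continuous"
    session_start_s: float = LIGHTS_ON_S
    session_end_s: float = LIGHTS_OFF_S
    stimulus_s: float = 0.0
    feed_s: float = 5.0
    iti_s: float = 2.0
    ratio: int = 1
    max_trials: int | None = None
    assumed_latency_s: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("autoshaping", "conditional", "continuous"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.feed_s <= 0:
            raise ValueError("feed_s must be positive")
        if self.iti_s < 0:
            raise ValueError("iti_s must be non-negative")
        if self.session_end_s <= self.session_start_s:
            raise ValueError("session_end_s must exceed session_start_s")

    @property
    def session_seconds(self) -> float:
        return self.session_end_s - self.session_start_s


def continuous_foraging_schedule() -> ScheduleConfig:
    """FR-1 closed economy: one peck -> 5 s food access, 2 s ITI, 0800-1715."""
    return ScheduleConfig(mode="continuous", feed_s=5.0, iti_s=2.0, ratio=1)


def autoshaping_schedule() -> ScheduleConfig:
    """Unconditional training: 15 s key light, 15 s food, 200 s ITI, 90 trials."""
    return ScheduleConfig(
        mode="autoshaping",
        session_start_s=8.5 * 3600,
        session_end_s=14.5 * 3600,
        stimulus_s=15.0,
        feed_s=15.0,
        iti_s=200.0,
        max_trials=90,
    )


def conditional_training_schedule() -> ScheduleConfig:
    """Conditional training: 15 s key light, 5 s food, 66 s ITI, 270 trials."""
    return ScheduleConfig(
        mode="conditional",
        session_start_s=8.5 * 3600,
        session_end_s=14.5 * 3600,
        stimulus_s=15.0,
        feed_s=5.0,
        iti_s=66.0,
        max_trials=270,
    )


@dataclass(frozen=True)
class BirdProfile:
    """Latent ground-truth parameters for one simulated bird.

    ``trajectory_coeffs`` are ascending-power cubic coefficients over centred
    time-of-day ``u = t_h - 8`` (hours since dawn), so ``coeffs[0]`` is the
    dawn mass. The constructor enforces that the trajectory interpolates the
    stated dawn mass at 0800 and dawn + gain at 1600.
    """

    bird_id: str
    sex: str
    tarsus_mm: float
    chip_ids: tuple[str, str]
    dawn_mass_g: float
    daily_gain_g: float
    trajectory_coeffs: tuple[float, float, float, float]
    visit_rate_dawn_per_h: float
    visit_rate_dusk_per_h: float
    noise_sd_g: float = 1.5
    mean_reinforcements_per_day: float = 260.0
    acquisition_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.dawn_mass_g <= 50:
            raise ValueError("dawn_mass_g must exceed 50 g")
        if self.daily_gain_g < 0:
            raise ValueError("daily_gain_g must be non-negative")
        if len(set(self.chip_ids)) != 2:
            raise ValueError("chip_ids must be two distinct labels")
        if self.visit_rate_dawn_per_h <= 0 or self.visit_rate_dusk_per_h <= 0:
            raise ValueError("visit rates must be positive")
        if not math.isclose(self.latent_mass(DAWN_H), self.dawn_mass_g,
                            abs_tol=1e-9):
            raise ValueError("trajectory at 0800 must equal dawn_mass_g")
        if not math.isclose(self.latent_mass(DUSK_H),
                            self.dawn_mass_g + self.daily_gain_g,
                            abs_tol=1e-9):
            raise ValueError("trajectory at 1600 must equal dawn + gain")

    def latent_mass(self, t_h: float | np.ndarray) -> float | np.ndarray:
        """True body mass (g) at time-of-day ``t_h`` hours."""
        u = np.asarray(t_h, dtype=float) - DAWN_H
        out = np.polynomial.polynomial.polyval(u, self.trajectory_coeffs)
        return float(out) if np.isscalar(t_h) else out

    def visit_rate(self, t_h: float | np.ndarray) -> float | np.ndarray:
        """Visit intensity (visits/h), declining linearly dawn -> lights-off."""
        t0, t1 = LIGHTS_ON_S / 3600.0, LIGHTS_OFF_S / 3600.0
        frac = (np.asarray(t_h, dtype=float) - t0) / (t1 - t0)
        out = (self.visit_rate_dawn_per_h
               + (self.visit_rate_dusk_per_h - self.visit_rate_dawn_per_h) * frac)
        return float(out) if np.isscalar(t_h) else out


@dataclass(frozen=True)
class SimConfig:
    """Study-level configuration for :func:`simulate_experiment`.

    Defaults reproduce the reference study design: 12 birds in two aviaries
    of six, one station per three birds (two per aviary), 11 days of
    continuous FR-1 foraging, lights 0800-1715, 6 Hz balances.
    """

    n_birds: int = 12
    n_days: int = 11
    n_stations: int | None = None  # default: ceil(n_birds / 3), i.e. 3:1
    lights_on_s: float = LIGHTS_ON_S
    lights_off_s: float = LIGHTS_OFF_S
    balance_hz: float = 6.0
    seed: int = 0
    schedule: ScheduleConfig = field(default_factory=continuous_foraging_schedule)
    # Balance contamination: probability that a single reading is replaced by
    # a uniform low value (bird with one foot on the hopper).
    bad_read_rate: float = 0.01
    # Visit-level mass offset (posture, crop content) shared by all readings
    # in one visit, on top of per-reading balance noise.
    posture_sd_g: float = 1.0
    # Near-zero baseline readings emitted around each visit so the stable-mass
    # detector's <10 g reset rule is exercised.
    baseline_n: int = 6
    intake_per_reinforcement_g: float = 0.095
    hopper_start_g: float = 400.0

    def __post_init__(self) -> None:
        if self.n_birds < 1 or self.n_days < 1:
            raise ValueError("n_birds and n_days must be >= 1")
        if self.balance_hz <= 0:
            raise ValueError("balance_hz must be positive")
        if self.lights_off_s <= self.lights_on_s:
            raise ValueError("lights_off_s must exceed lights_on_s")

    @property
    def stations(self) -> list[str]:
        k = self.n_stations or math.ceil(self.n_birds / 3)
        return [f"S{i + 1}" for i in range(k)]


@dataclass
class SimBundle:
    """Raw log bundle plus ground truth from one simulated experiment.

    All frames are time-ordered within station and day. ``truth_days`` holds
    per bird-day visit/peck counts and latent dawn/dusk masses;
    ``truth_hourly`` holds the latent trajectory sampled on integer hours
    0800-1600.
    """

    profiles: list[BirdProfile]
    config: SimConfig
    ring_map: pd.DataFrame        # chip_id, bird_id
    balance: pd.DataFrame         # day, station_id, t, mass_g
    rfid: pd.DataFrame            # day, station_id, t, chip_id
    pecks: pd.DataFrame           # day, station_id, t, bird_id, reinforced
    hopper: pd.DataFrame          # aviary_id, day, hopper_start_g, hopper_end_g, spill_g, n_birds
    truth_days: pd.DataFrame      # bird_id, day, true_visits, true_reinforcements, ...
    truth_hourly: pd.DataFrame    # bird_id, day, hour, latent_mass_g

    def station_of(self, bird_id: str) -> str:
        idx = [p.bird_id for p in self.profiles].index(bird_id)
        stations = self.config.stations
        return stations[idx % len(stations)]


# Peak magnitude of x(1-x)(x-1/2) on [0,1]; normalises the inflection basis
# so its coefficient is an amplitude in grams.
_PEAK3 = 3 ** 0.5 / 36.0


def _trajectory_coeffs(dawn_mass_g: float, daily_gain_g: float,
                       hump_g: float, inflect_g: float) -> tuple[float, ...]:
    """Cubic coefficients over u = t_h - 8 hitting dawn at u=0, dawn+gain at u=8.

    The trajectory is the linear dawn-to-dusk gain plus two endpoint-anchored
    bumps in x = u/8: a concave hump ``hump_g * 4x(1-x)`` (peak deflection
    ``hump_g`` grams at midday, giving the decelerating gain of birds that
    forage hardest early) and a normalised inflection term
    ``inflect_g * x(1-x)(x-1/2)/peak`` (peak deflection ``inflect_g`` grams,
    tilting toward a late slow-down or a pre-dusk uptick). Both vanish at
    dawn and dusk, so the endpoint constraints hold identically.
    """
    g = daily_gain_g
    cx1 = g + 4.0 * hump_g - 0.5 * inflect_g / _PEAK3
    cx2 = -4.0 * hump_g + 1.5 * inflect_g / _PEAK3
    cx3 = -inflect_g / _PEAK3
    return (dawn_mass_g, cx1 / 8.0, cx2 / 64.0, cx3 / 512.0)


def make_bird_profiles(n: int, seed: int) -> list[BirdProfile]:
    """Draw ``n`` bird profiles with latent parameters in the observed cohort ranges.

    Deterministic given ``seed``. Sexes alternate M/F; males get a ~1 mm
    longer tarsus on average. Each bird receives two distinct chip ids.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        sex = "M" if i % 2 == 0 else "F"
        dawn = rng.uniform(*DAWN_MASS_RANGE_G)
        gain = rng.uniform(*DAILY_GAIN_RANGE_G)
        # gram-scale shape deflections; the mix spans bird-days best fitted
        # by linear, quadratic, and cubic trajectories
        hump = rng.uniform(0.1, 1.5)
        inflect = rng.uniform(-0.6, 0.6)
        profiles.append(BirdProfile(
            bird_id=f"B{i + 1:02d}",
            sex=sex,
            tarsus_mm=float(rng.normal(29.5 + (1.0 if sex == "M" else 0.0), 0.7)),
            chip_ids=(f"C{i + 1:03d}A", f"C{i + 1:03d}B"),
            dawn_mass_g=float(dawn),
            daily_gain_g=float(gain),
            trajectory_coeffs=_trajectory_coeffs(float(dawn), float(gain),
                                                 float(hump), float(inflect)),
            visit_rate_dawn_per_h=float(rng.uniform(9.0, 16.0)),
            visit_rate_dusk_per_h=float(rng.uniform(2.5, 6.0)),
            noise_sd_g=1.5,
            mean_reinforcements_per_day=float(rng.uniform(*REINFORCEMENTS_RANGE)),
            acquisition_rate=float(rng.uniform(0.5, 2.0)),
        ))
    return profiles


def _sample_visit_times(rng: np.random.Generator, profile: BirdProfile,
                        t0_h: float, t1_h: float) -> np.ndarray:
    """Inhomogeneous Poisson visit start times (hours) by thinning."""
    lam_max = max(profile.visit_rate_dawn_per_h, profile.visit_rate_dusk_per_h)
    n = rng.poisson(lam_max * (t1_h - t0_h))
    ts = np.sort(rng.uniform(t0_h, t1_h, n))
    keep = rng.uniform(0.0, lam_max, n) < profile.visit_rate(ts)
    return ts[keep]


def _aviary_of_station(station_idx: int) -> str:
    # Two stations (six birds) per aviary, mirroring the reference design.
    return f"A{station_idx // 2 + 1}"


def simulate_experiment(profiles: list[BirdProfile],
                        config: SimConfig) -> SimBundle:
    """Simulate a multi-day closed-economy run and return logs plus ground truth.

    Per station and day, a visiting bird produces 6 Hz balance readings
    centred on its latent trajectory value (plus a per-visit posture offset
    and per-reading Gaussian noise), interleaved with near-zero baseline
    readings between visits; RFID reads are emitted at ~1 Hz while the bird
    occupies the perch; pecks follow the FR-1 cycle and respect the station's
    feed/ITI lockout, so two reinforcements on one station are never closer
    than latency + feed + ITI seconds. Overlapping visits to one perch are
    resolved by dropping the later arrival (a perch holds one bird).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(config.seed)
    stations = config.stations
    sched = config.schedule
    dt = 1.0 / config.balance_hz
    cycle = sched.assumed_latency_s + sched.feed_s + sched.iti_s
    t0_h = config.lights_on_s / 3600.0
    t1_h = config.lights_off_s / 3600.0

    ring_rows = [(chip, p.bird_id) for p in profiles for chip in p.chip_ids]
    ring_map = pd.DataFrame(ring_rows, columns=["chip_id", "bird_id"])

    # Expected visits/day per bird; sets visit-duration scale so that total
    # pecks land near the profile's reinforcement target.
    sigma_dur = 0.9
    bal_rows: list[tuple] = []
    rfid_rows: list[tuple] = []
    peck_rows: list[tuple] = []
    hopper_rows: list[tuple] = []
    truth_day_rows: list[tuple] = []
    truth_hour_rows: list[tuple] = []

    hours = np.arange(int(DAWN_H), int(DUSK_H) + 1)

    for day in range(1, config.n_days + 1):
        # visits per station: (start_s, end_s, bird_index)
        station_visits: dict[str, list[tuple[float, float, int]]] = {
            s: [] for s in stations}
        for i, p in enumerate(profiles):
            st = stations[i % len(stations)]
            starts_h = _sample_visit_times(rng, p, t0_h, t1_h)
            exp_visits = (p.visit_rate_dawn_per_h + p.visit_rate_dusk_per_h) \
                / 2.0 * (t1_h - t0_h)
            mean_dur = cycle * p.mean_reinforcements_per_day / max(exp_visits, 1.0)
            median_dur = max(mean_dur / math.exp(sigma_dur ** 2 / 2.0), 4.0)
            durs = rng.lognormal(math.log(median_dur), sigma_dur,
                                 len(starts_h)).clip(2.0, 600.0)
            for s_h, d in zip(starts_h, durs):
                start = s_h * 3600.0
                end = min(start + d, config.lights_off_s)
                if end - start >= 2.0:
                    station_visits[st].append((start, end, i))

        day_visits = {p.bird_id: 0 for p in profiles}
        day_pecks = {p.bird_id: 0 for p in profiles}

        for st_idx, st in enumerate(stations):
            visits = sorted(station_visits[st])
            kept: list[tuple[float, float, int]] = []
            cur_end = -np.inf
            for start, end, i in visits:
                if start >= cur_end + 1.0:   # one bird per perch at a time
                    kept.append((start, end, i))
                    cur_end = end
            station_ready = config.lights_on_s  # key lit from session start
            for start, end, i in kept:
                p = profiles[i]
                day_visits[p.bird_id] += 1
                # balance stream for the visit
                times = np.arange(start, end, dt)
                offset = rng.normal(0.0, config.posture_sd_g)
                latent = p.latent_mass(times / 3600.0)
                masses = latent + offset + rng.normal(0.0, p.noise_sd_g,
                                                      len(times))
                bad = rng.random(len(times)) < config.bad_read_rate
                masses[bad] = rng.uniform(15.0, 45.0, int(bad.sum()))
                bal_rows.extend(zip([day] * len(times), [st] * len(times),
                                    times, masses))
                # trailing near-zero baseline burst (bird leaves the perch)
                base_t = times[-1] + dt + dt * np.arange(config.baseline_n)
                base_t = base_t[base_t <= config.lights_off_s]
                base_m = np.abs(rng.normal(0.0, 2.0, len(base_t))).clip(0.0, 9.5)
                bal_rows.extend(zip([day] * len(base_t), [st] * len(base_t),
                                    base_t, base_m))
                # RFID reads at ~1 Hz while the bird is on the perch
                read_t = np.arange(start, end, 1.0)
                chips = np.asarray(p.chip_ids)[
                    rng.integers(0, 2, len(read_t))]
                rfid_rows.extend(zip([day] * len(read_t), [st] * len(read_t),
                                     read_t, chips))
                # FR-1 pecks: station lockout persists across visits
                t_peck = max(start, station_ready) + sched.assumed_latency_s
                while t_peck <= end and t_peck <= sched.session_end_s:
                    peck_rows.append((day, st, t_peck, p.bird_id, True))
                    day_pecks[p.bird_id] += 1
                    station_ready = t_peck + sched.feed_s + sched.iti_s
                    t_peck = station_ready + sched.assumed_latency_s

        for i, p in enumerate(profiles):
            dawn = p.latent_mass(DAWN_H)
            dusk = p.latent_mass(DUSK_H)
            truth_day_rows.append((
                p.bird_id, day, day_visits[p.bird_id], day_pecks[p.bird_id],
                dawn, dusk, dusk - dawn,
                day_pecks[p.bird_id] * config.intake_per_reinforcement_g,
            ))
            for h in hours:
                truth_hour_rows.append((p.bird_id, day, int(h),
                                        p.latent_mass(float(h))))

        aviaries = sorted({_aviary_of_station(k) for k in range(len(stations))})
        for av in aviaries:
            members = [p.bird_id for i, p in enumerate(profiles)
                       if _aviary_of_station(i % len(stations)) == av]
            consumed = sum(day_pecks[b] for b in members) \
                * config.intake_per_reinforcement_g
            spill = float(rng.uniform(0.0, 5.0))
            hopper_rows.append((av, day, config.hopper_start_g,
                                config.hopper_start_g - consumed - spill,
                                spill, len(members)))

    balance = pd.DataFrame(bal_rows,
                           columns=["day", "station_id", "t", "mass_g"])
    balance = balance.sort_values(["day", "station_id", "t"],
                                  kind="stable").reset_index(drop=True)
    rfid = pd.DataFrame(rfid_rows,
                        columns=["day", "station_id", "t", "chip_id"])
    rfid = rfid.sort_values(["day", "station_id", "t"],
                            kind="stable").reset_index(drop=True)
    pecks = pd.DataFrame(peck_rows,
                         columns=["day", "station_id", "t", "bird_id",
                                  "reinforced"])
    hopper = pd.DataFrame(hopper_rows,
                          columns=["aviary_id", "day", "hopper_start_g",
                                   "hopper_end_g", "spill_g", "n_birds"])
    truth_days = pd.DataFrame(truth_day_rows,
                              columns=["bird_id", "day", "true_visits",
                                       "true_reinforcements", "true_dawn_g",
                                       "true_dusk_g", "true_gain_g",
                                       "true_intake_g"])
    truth_hourly = pd.DataFrame(truth_hour_rows,
                                columns=["bird_id", "day", "hour",
                                         "latent_mass_g"])
    return SimBundle(profiles=list(profiles), config=config, ring_map=ring_map,
                     balance=balance, rfid=rfid, pecks=pecks, hopper=hopper,
                     truth_days=truth_days, truth_hourly=truth_hourly)


def simulate_training_sessions(profiles: list[BirdProfile],
                               schedule: ScheduleConfig,
                               n_sessions: int,
                               seed: int) -> pd.DataFrame:
    """Simulate trial-structured operant training sessions.

    Each session has ``schedule.max_trials`` trials (90 for autoshaping, 270
    for conditional training). On each trial every bird independently pecks
    with probability ``1 - exp(-acquisition_rate * session)``, so acquisition
    rises across sessions and a bird with acquisition_rate 0 never pecks.

    Returns a long frame (session, trial, bird_id, pecked).
    """
    if schedule.mode == "continuous":
        raise ValueError("training simulation requires an autoshaping or "
                         "conditional schedule")
    if schedule.max_trials is None:
        raise ValueError("training schedule must set max_trials")
    rng = np.random.default_rng(seed)
    rows = []
    for session in range(1, n_sessions + 1):
        for trial in range(1, schedule.max_trials + 1):
            for p in profiles:
                prob = 1.0 - math.exp(-p.acquisition_rate * session)
                rows.append((session, trial, p.bird_id,
                             bool(rng.random() < prob)))
    return pd.DataFrame(rows, columns=["session", "trial", "bird_id",
                                       "pecked"])


def profiles_with(profiles: list[BirdProfile], **changes) -> list[BirdProfile]:
    """Return copies of ``profiles`` with fields overridden (e.g. noise_sd_g=0)."""
    return [replace(p, **changes) for p in profiles]
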