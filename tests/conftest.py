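"""Shared fixtures: one full-size simulated cohort, processed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from sfskit import stable_mass, synthetic_data, trajectory


@pytest.fixture(scope="session")
def profiles12():
    return synthetic_data.make_bird_profiles(12, seed=7)


@pytest.fixture(scope="session")
def bundle(profiles12):
    """12 birds, 11 days, full generator defaults (seed 7)."""
    cfg = synthetic_data.SimConfig(seed=7)
    return synthetic_data.simulate_experiment(profiles12, cfg)


@pytest.fixture(scope="session")
def attributed_masses(bundle):
    """Stable masses detected, attributed, and gross-filtered from `bundle`."""
    events = stable_mass.detect_stable_masses(bundle.balance)
    attr = stable_mass.attribute_masses(events, bundle.rfid, bundle.ring_map)
    retained, _ = stable_mass.filter_gross_outliers(attr.masses)
    return retained


@pytest.fixture(scope="session")
def fits(attributed_masses):
    return trajectory.fit_bird_days(attributed_masses)


def brute_force_stable_masses(t, mass, *, min_mass_g=50.0, range_g=5.0,
                              window_n=5, reset_below_g=10.0):
    """Literal reference detector: scan every window, apply the lockout rule.

    Walks the stream reading by reading, re-arming on any value below
    ``reset_below_g`` and, while armed, emitting at the first window of
    ``window_n`` consecutive readings all above ``min_mass_g`` spanning at
    most ``range_g``. Kept deliberately naive and independent of the
    production implementation.
    """
    t = np.asarray(t, dtype=float)
    m = np.asarray(mass, dtype=float)
    events = []
    armed = True
    for j in range(len(m)):
        if m[j] < reset_below_g:
            armed = True
        if armed and j >= window_n - 1:
            win = m[j - window_n + 1: j + 1]
            if (win > min_mass_g).all() and win.max() - win.min() <= range_g:
                events.append((t[j], win.mean()))
                armed = False
    return events


def random_balance_stream(rng, n):
    """A stream mixing baseline, mid-range, plausible-mass and junk segments."""
    vals = []
    while len(vals) < n:
        kind = rng.integers(0, 4)
        seg = rng.integers(1, 12)
        if kind == 0:
            vals.extend(rng.uniform(0, 10, seg))        # baseline
        elif kind == 1:
            vals.extend(rng.uniform(10, 52, seg))       # bad perching
        elif kind == 2:
            centre = rng.uniform(55, 118)
            vals.extend(centre + rng.normal(0, rng.uniform(0.5, 4), seg))
        else:
            vals.extend(rng.uniform(45, 130, seg))      # junk
    vals = np.asarray(vals[:n])
    return np.arange(n) / 6.0, vals
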