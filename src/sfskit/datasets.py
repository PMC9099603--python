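"""Bundled reference data.

``load_cohort_descriptives`` returns the per-bird descriptive statistics
(mean ± sd over 11 study days) published for the original 12-bird,
two-aviary closed-economy cohort: reinforcements earned per day, stable
masses retained per day, fitted dawn/noon/dusk masses, daily gain, and
nightly loss. These serve as the reference scale for the synthetic-data
generator and as input for cohort-level recomputations (grand means,
sex contrasts, dawn-dusk and gain-loss correlations).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cohort_descriptives"]


def load_cohort_descriptives() -> pd.DataFrame:
    """Per-bird cohort descriptive statistics (one row per bird, n=12)."""
    ref = resources.files("sfskit") / "data" / "cohort_descriptives.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"aviary_id": str, "bird_id": str})
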