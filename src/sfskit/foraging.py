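"""Foraging-effort summaries: reinforcement counts and rates, schedule
capacity, aviary-level food consumption, and training acquisition.

Under the FR-1 closed economy every peck at a lit key earns one
reinforcement (5 s of hopper access), so peck counts and reinforcement
counts coincide and per-bird effort is simply the attributed peck log.
Food consumption is only measurable at the aviary level (hopper mass change
minus spill-tray crumb) and is expressed per bird per day for comparison
across group sizes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from sfskit.synthetic_data import LIGHTS_OFF_S, LIGHTS_ON_S, ScheduleConfig

__all__ = [
    "count_reinforcements",
    "hourly_rates",
    "max_daily_reinforcements",
    "consumption_per_bird",
    "acquisition_summary",
]


def count_reinforcements(pecks: pd.DataFrame, *,
                         session_start_s: float = LIGHTS_ON_S,
                         session_end_s: float = LIGHTS_OFF_S,
                         birds: list[str] | None = None,
                         days: list[int] | None = None) -> pd.DataFrame:
    """Per-bird-per-day reinforcement totals and per-hour session rates.

    ``pecks`` needs columns ``bird_id``, ``day``, ``t`` and (optionally)
    ``reinforced``; only reinforced pecks are counted. Passing ``birds``/
    ``days`` fills in explicit zero rows for bird-days without any pecks.
    """
    df = pecks
    if "reinforced" in df.columns:
        df = df[df["reinforced"]]
    if df.empty:
        counts = pd.DataFrame(columns=["bird_id", "day", "reinforcements"])
    else:
        counts = (df.groupby(["bird_id", "day"]).size()
                  .rename("reinforcements").reset_index())
    if birds is not None and days is not None:
        full = pd.MultiIndex.from_product([sorted(birds), sorted(days)],
                                          names=["bird_id", "day"])
        counts = (counts.set_index(["bird_id", "day"])
                  .reindex(full, fill_value=0).reset_index())
    session_h = (session_end_s - session_start_s) / 3600.0
    counts["rate_per_h"] = counts["reinforcements"] / session_h
    return counts.sort_values(["bird_id", "day"]).reset_index(drop=True)


def hourly_rates(pecks: pd.DataFrame, *,
                 session_start_s: float = LIGHTS_ON_S,
                 session_end_s: float = LIGHTS_OFF_S) -> pd.DataFrame:
    """Reinforcement rate (per hour) in left-closed hour bins from 0800.

    The final partial bin (1700-1715) is scaled by its width so all rows are
    directly comparable as rates per hour.
    """
    df = pecks
    if "reinforced" in df.columns:
        df = df[df["reinforced"]]
    start_h = session_start_s / 3600.0
    end_h = session_end_s / 3600.0
    edges = np.arange(math.floor(start_h), math.ceil(end_h) + 1, 1.0)
    edges = np.clip(edges, start_h, end_h)
    widths = np.diff(edges)
    rows = []
    for (bird, day), grp in df.groupby(["bird_id", "day"]):
        hist, _ = np.histogram(grp["t"].to_numpy() / 3600.0, bins=edges)
        for lo, w, c in zip(edges[:-1], widths, hist):
            if w > 0:
                rows.append((bird, day, int(lo), c / w))
    return pd.DataFrame(rows, columns=["bird_id", "day", "hour",
                                       "rate_per_h"])


def max_daily_reinforcements(schedule: ScheduleConfig) -> int:
    """Theoretical daily reinforcement capacity of one station.

    Assumes a bird always pecks ``assumed_latency_s`` after the key lights,
    so each reinforcement cycle takes latency + feed + ITI seconds:
    ``floor(session_seconds / cycle)``.
    """
    cycle = schedule.assumed_latency_s + schedule.feed_s + schedule.iti_s
    if cycle <= 0:
        raise ValueError("reinforcement cycle length must be positive")
    return int(schedule.session_seconds // cycle)


def consumption_per_bird(records: pd.DataFrame) -> pd.DataFrame:
    """Aviary-day crumb consumption, expressed as g per bird per day.

    ``records`` columns: aviary_id, day, hopper_start_g, hopper_end_g,
    spill_g, n_birds. Consumption is start - end - spill; negative values
    (spill exceeding the hopper mass change) are physically impossible and
    flagged in ``qc_flag`` rather than silently clipped.
    """
    if (records["n_birds"] <= 0).any():
        raise ValueError("n_birds must be positive")
    out = records.copy()
    out["consumption_g"] = (out["hopper_start_g"] - out["hopper_end_g"]
                            - out["spill_g"])
    out["g_per_bird_day"] = out["consumption_g"] / out["n_birds"]
    out["qc_flag"] = out["consumption_g"] < 0
    return out


def acquisition_summary(training: pd.DataFrame, *,
                        min_pecked_trials: int = 3) -> pd.DataFrame:
    """Per-bird, per-session counts of trials with at least one peck.

    The whole aviary progresses to the next training phase only when every
    bird pecked on at least ``min_pecked_trials`` trials in a session;
    ``progressed`` marks sessions meeting that criterion.
    """
    counts = (training[training["pecked"]]
              .groupby(["session", "bird_id"]).size()
              .rename("pecked_trials"))
    sessions = sorted(training["session"].unique())
    birds = sorted(training["bird_id"].unique())
    full = pd.MultiIndex.from_product([sessions, birds],
                                      names=["session", "bird_id"])
    counts = counts.reindex(full, fill_value=0).reset_index()
    progressed = (counts.groupby("session")["pecked_trials"]
                  .agg(lambda s: bool((s >= min_pecked_trials).all()))
                  .rename("progressed").reset_index())
    return counts.merge(progressed, on="session")
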