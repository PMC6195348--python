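"""Behavioral metrics of the phenotyping battery.

Nineteen metrics across five assays, each a pure function of its event or
occupancy inputs.  Ratio-type metrics (preferences, commitment) lie in
[0, 1]; Novelty-Seeking and Grooming Ratio are ratios of differences and are
unbounded below but never exceed 1.  Undefined values (zero denominators,
missing sessions) propagate as NaN and are treated as missing downstream.

Metric naming: ``<task prefix>_<measure>`` with prefixes EPM (elevated plus
maze), GR (grooming), SC (social chamber), YM (Y-maze) and EB (eyeblink).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import Trajectory, zone_labels, ArenaGeometry

__all__ = [
    "GroomingLog",
    "filter_grooming",
    "grooming_summaries",
    "grooming_ratio",
    "ymaze_metrics",
    "social_metrics",
    "epm_metrics",
    "first_choice_arm",
    "metric_matrix_to_csv",
    "metric_matrix_from_csv",
]


# ---------------------------------------------------------------------------
# Grooming
# ---------------------------------------------------------------------------

@dataclass
class GroomingLog:
    """Scored grooming events: (start s, end s, condition) tuples."""

    events: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        by_cond: dict[str, list[tuple[float, float]]] = {}
        for start, end, cond in self.events:
            if end <= start:
                raise ValueError(f"event ({start}, {end}) has end <= start")
            by_cond.setdefault(cond, []).append((start, end))
        for cond, evs in by_cond.items():
            evs = sorted(evs)
            for (s1, e1), (s2, _) in zip(evs, evs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping events in {cond!r} session")

    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e, _ in self.events])


def filter_grooming(log: GroomingLog, min_dur_s: float = 1.0) -> GroomingLog:
    """Drop events strictly shorter than ``min_dur_s`` (default 1 s)."""
    return GroomingLog(
        events=[ev for ev in log.events if ev[1] - ev[0] >= min_dur_s]
    )


def grooming_summaries(log: GroomingLog) -> dict[str, float]:
    """Cumulative time, event count, mean bout length, mean inter-event gap.

    An empty log yields count 0, cumulative time 0, and NaN for the means.
    """
    if not log.events:
        return {"cumulative_s": 0.0, "n_events": 0,
                "mean_bout_s": np.nan, "mean_gap_s": np.nan}
    d = log.durations()
    ordered = sorted((s, e) for s, e, _ in log.events)
    gaps = [s2 - e1 for (_, e1), (s2, _) in zip(ordered, ordered[1:])]
    return {
        "cumulative_s": float(d.sum()),
        "n_events": int(len(d)),
        "mean_bout_s": float(d.mean()),
        "mean_gap_s": float(np.mean(gaps)) if gaps else np.nan,
    }


def grooming_ratio(avg_saline_s: float, avg_cno_s: float) -> float:
    """(AVG_saline - AVG_CNO) / AVG_saline; NaN when the saline mean is 0."""
    if avg_saline_s == 0 or not np.isfinite(avg_saline_s):
        return np.nan
    return (avg_saline_s - avg_cno_s) / avg_saline_s


# ---------------------------------------------------------------------------
# Y-maze
# ---------------------------------------------------------------------------

def _slope(y: np.ndarray) -> float:
    """Least-squares slope of y against session number 1..len(y)."""
    x = np.arange(1, len(y) + 1, dtype=float)
    return float(np.polyfit(x, np.asarray(y, dtype=float), 1)[0])


def ymaze_metrics(acq: list[float] | None, rd1: list[float] | None,
                  rd2: list[float] | None) -> dict[str, float]:
    """Nine Y-maze learning metrics from per-session percent-correct scores.

    ``acq``, ``rd1`` and ``rd2`` each hold four sessions of percent-correct
    first choices (acquisition, reversal day 1, reversal day 2).  Initial
    metrics are session 1; final metrics average late sessions (3-4 for
    acquisition/reversal 1; all four for reversal 2); multisession metrics
    are the least-squares slope over sessions 1-3.  A missing day flags its
    metrics NaN.
    """
    out = {
        "YM_Initial Learning": np.nan, "YM_Final Learning": np.nan,
        "YM_Multisession Learning": np.nan,
        "YM_Initial Reversal 1": np.nan, "YM_Final Reversal 1": np.nan,
        "YM_Multisession Reversal 1": np.nan,
        "YM_Initial Reversal 2": np.nan, "YM_Final Reversal 2": np.nan,
    }

    def complete(day):
        return day is not None and len(day) == 4 and np.all(np.isfinite(day))

    if complete(acq):
        a = np.asarray(acq, dtype=float)
        if not np.all((a >= 0) & (a <= 100)):
            raise ValueError("percent correct must lie in [0, 100]")
        out["YM_Initial Learning"] = a[0]
        out["YM_Final Learning"] = (a[2] + a[3]) / 2
        out["YM_Multisession Learning"] = _slope(a[:3])
    if complete(rd1):
        r = np.asarray(rd1, dtype=float)
        out["YM_Initial Reversal 1"] = r[0]
        out["YM_Final Reversal 1"] = (r[2] + r[3]) / 2
        out["YM_Multisession Reversal 1"] = _slope(r[:3])
    if complete(rd2):
        r = np.asarray(rd2, dtype=float)
        out["YM_Initial Reversal 2"] = r[0]
        out["YM_Final Reversal 2"] = float(r.mean())
    return out


def first_choice_arm(traj: Trajectory, arena: ArenaGeometry,
                     start_zone: str = "start_arm",
                     center_zone: str = "center") -> str | None:
    """First non-start arm the centroid enters (scores a Y-maze trial)."""
    for label in zone_labels(traj, arena):
        if label is not None and label not in (start_zone, center_zone):
            return label
    return None


# ---------------------------------------------------------------------------
# Social chamber
# ---------------------------------------------------------------------------

def social_metrics(time_near_mouse_s: float, time_near_object_s: float,
                   baseline_entrances: tuple[float, float],
                   test_entrances: tuple[float, float],
                   baseline_distance_m: float,
                   test_distance_m: float) -> dict[str, float]:
    """Four social-chamber metrics.

    Social Preference = TimeNearM / (TimeNearM + TimeNearO).
    Novelty-Seeking = ((EntrM_bs + EntrO_bs) - (EntrM_test + EntrO_test))
    / (EntrM_bs + EntrO_bs) — a drop in side-chamber entrances from baseline
    to test, relative to baseline.  Zero denominators yield NaN.
    """
    interact = time_near_mouse_s + time_near_object_s
    preference = time_near_mouse_s / interact if interact > 0 else np.nan
    bs = baseline_entrances[0] + baseline_entrances[1]
    test = test_entrances[0] + test_entrances[1]
    novelty = (bs - test) / bs if bs > 0 else np.nan
    return {
        "SC_Social Preference": preference,
        "SC_Novelty-Seeking": novelty,
        "SC_Baseline Distance": baseline_distance_m,
        "SC_Test Distance": test_distance_m,
    }


# ---------------------------------------------------------------------------
# Elevated plus-maze
# ---------------------------------------------------------------------------

def epm_metrics(time_open_s: float, time_closed_s: float,
                time_central_s: float, central_entrances: float,
                open_full: int, open_jittery: int,
                distance_cm: float) -> dict[str, float]:
    """Five plus-maze metrics.

    Open-Arm Preference = Timeopen / (Timeclosed + Timeopen);
    Commitment = full open-arm entrances over full + jittery;
    Exploration Time/Entrances are the central crossroads occupancy and entry
    count; Distance is the session path length in cm.
    """
    arm_total = time_open_s + time_closed_s
    pref = time_open_s / arm_total if arm_total > 0 else np.nan
    entr_total = open_full + open_jittery
    commitment = open_full / entr_total if entr_total > 0 else np.nan
    return {
        "EPM_Open-Arm Preference": pref,
        "EPM_Commitment": commitment,
        "EPM_Exploration Time": time_central_s,
        "EPM_Exploration Entrances": central_entrances,
        "EPM_Distance": distance_cm,
    }


# ---------------------------------------------------------------------------
# Metric-matrix I/O (tidy long format)
# ---------------------------------------------------------------------------

def metric_matrix_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a wide (mouse, group, metrics...) table as tidy long CSV."""
    long = df.melt(id_vars=["mouse", "group"], var_name="metric",
                   value_name="value")
    long.to_csv(path, index=False)


def metric_matrix_from_csv(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path)
    wide = long.pivot(index=["mouse", "group"], columns="metric",
                      values="value").reset_index()
    wide.columns.name = None
    return wide
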