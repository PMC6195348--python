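"""Conditioned-response detection from eyelid traces and spike-train summaries.

A delay eyeblink-conditioning session mixes CS-US paired trials, CS-only
probe trials and US-only trials.  US-only trials establish the full range of
the unconditioned response (full eye closure); every trace is then rescaled
so baseline maps to 0 and full closure to 1.  A counted trial (paired or
CS-only) is scored as a conditioned response (CR) when the normalized trace
exceeds 0.15 — 15% of the full UR range — in the window 100-280 ms after CS
onset.  The session-level response probability is the fraction of counted
trials scored as CRs.

Spike trains are summarized by the firing frequency FF = (N-1)/(t_N - t_1)
and the local coefficient of variation
CV2 = mean_i 2|ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i),
which is 0 for a perfectly regular train and about 1 for Poisson firing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EyeblinkSession",
    "normalize_traces",
    "detect_cr",
    "response_probability",
    "spike_summaries",
    "CR_THRESHOLD",
    "CR_WINDOW_S",
]

CR_THRESHOLD = 0.15                 # fraction of full UR range
CR_WINDOW_S = (0.100, 0.280)        # after CS onset; half-open (lo, hi]
BASELINE_WINDOW_S = 0.200           # pre-CS (or trial-start) baseline


@dataclass
class EyeblinkSession:
    """Eyelid traces segmented into typed trials.

    ``traces`` is (n_trials, n_samples) in raw voltage-proportional units;
    ``cs_onset_s`` is NaN for US-only trials.
    """

    trial_types: np.ndarray     # {"paired", "cs_only", "us_only"}
    cs_onset_s: np.ndarray
    traces: np.ndarray
    sample_rate: float
    us_onset_s: float | None = None

    def __post_init__(self) -> None:
        for i, typ in enumerate(self.trial_types):
            has_cs = np.isfinite(self.cs_onset_s[i])
            if typ in ("paired", "cs_only") and not has_cs:
                raise ValueError(f"trial {i} ({typ}) lacks a CS onset")
            if typ == "us_only" and has_cs:
                raise ValueError(f"US-only trial {i} must not carry a CS")

    @property
    def n_trials(self) -> int:
        return len(self.trial_types)

    def counted_indices(self) -> np.ndarray:
        """Counted trials: paired + CS-only."""
        return np.flatnonzero(np.isin(self.trial_types, ["paired", "cs_only"]))

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, meta_path: str | Path, traces_path: str | Path) -> None:
        pd.DataFrame({
            "trial_id": np.arange(self.n_trials),
            "type": self.trial_types,
            "cs_onset_s": self.cs_onset_s,
            "sample_rate_hz": self.sample_rate,
        }).to_csv(meta_path, index=False)
        pd.DataFrame(self.traces).to_csv(traces_path, index=False)

    @classmethod
    def from_csv(cls, meta_path: str | Path, traces_path: str | Path) -> "EyeblinkSession":
        meta = pd.read_csv(meta_path)
        traces = pd.read_csv(traces_path).to_numpy()
        return cls(
            trial_types=meta["type"].to_numpy(dtype=object),
            cs_onset_s=meta["cs_onset_s"].to_numpy(dtype=float),
            traces=traces,
            sample_rate=float(meta["sample_rate_hz"].iloc[0]),
        )


def _baseline(trace: np.ndarray, fs: float, cs_onset_s: float) -> float:
    """Mean of the 200 ms before the CS (or from trial start for US-only)."""
    if np.isfinite(cs_onset_s):
        hi = int(round(cs_onset_s * fs))
        lo = max(0, hi - int(round(BASELINE_WINDOW_S * fs)))
    else:
        lo, hi = 0, int(round(BASELINE_WINDOW_S * fs))
    if hi <= lo:
        raise ValueError("no samples available for the baseline window")
    return float(trace[lo:hi].mean())


def normalize_traces(session: EyeblinkSession) -> np.ndarray:
    """Rescale every trace to fraction-of-full-UR units.

    The full range is the mean over US-only trials of the peak UR deflection
    above that trial's baseline; each trace is shifted by its own baseline
    and divided by that range (baseline -> 0, full closure -> 1).
    """
    us_only = np.flatnonzero(session.trial_types == "us_only")
    if len(us_only) == 0:
        raise ValueError("session has no US-only trials to define full closure")
    fs = session.sample_rate
    peaks = []
    for i in us_only:
        b = _baseline(session.traces[i], fs, session.cs_onset_s[i])
        peaks.append(session.traces[i].max() - b)
    full_range = float(np.mean(peaks))
    if full_range <= 0:
        raise ValueError("non-positive full UR range")
    out = np.empty_like(session.traces, dtype=float)
    for i in range(session.n_trials):
        b = _baseline(session.traces[i], fs, session.cs_onset_s[i])
        out[i] = (session.traces[i] - b) / full_range
    return out


def detect_cr(normalized_trace: np.ndarray, cs_onset_s: float,
              sample_rate: float, threshold: float = CR_THRESHOLD) -> bool:
    """CR iff the trace exceeds the threshold within (CS+100, CS+280] ms."""
    lo_s = cs_onset_s + CR_WINDOW_S[0]
    hi_s = cs_onset_s + CR_WINDOW_S[1]
    # half-open window (lo, hi]
    lo = int(np.floor(lo_s * sample_rate)) + 1
    hi = int(np.floor(hi_s * sample_rate)) + 1
    if lo < 0 or hi > len(normalized_trace):
        raise ValueError("CR window lies outside the recorded trace")
    return bool(normalized_trace[lo:hi].max() > threshold)


def response_probability(session: EyeblinkSession,
                         threshold: float = CR_THRESHOLD) -> float:
    """Fraction of counted (paired + CS-only) trials scored as CRs."""
    counted = session.counted_indices()
    if len(counted) == 0:
        raise ValueError("no counted trials")
    normalized = normalize_traces(session)
    n_cr = sum(
        detect_cr(normalized[i], session.cs_onset_s[i], session.sample_rate,
                  threshold)
        for i in counted
    )
    return n_cr / len(counted)


def score_session(session: EyeblinkSession,
                  threshold: float = CR_THRESHOLD) -> pd.DataFrame:
    """Per-counted-trial CR calls as a tidy table."""
    normalized = normalize_traces(session)
    rows = []
    for i in session.counted_indices():
        rows.append({
            "trial_id": int(i),
            "type": session.trial_types[i],
            "cr": detect_cr(normalized[i], session.cs_onset_s[i],
                            session.sample_rate, threshold),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def spike_summaries(spike_times: np.ndarray) -> tuple[float, float]:
    """(firing frequency Hz, mean CV2) of a strictly increasing spike train.

    FF needs at least two spikes; CV2 at least three (two adjacent ISIs).
    CV2 lies in [0, 2) and is invariant under uniform time rescaling.
    """
    t = np.asarray(spike_times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 spikes for firing frequency")
    if not np.all(np.diff(t) > 0):
        raise ValueError("spike times must be strictly increasing")
    ff = (len(t) - 1) / (t[-1] - t[0])
    if len(t) < 3:
        return float(ff), float("nan")
    isi = np.diff(t)
    cv2 = np.mean(2.0 * np.abs(np.diff(isi)) / (isi[1:] + isi[:-1]))
    return float(ff), float(cv2)
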