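"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be produced here: arena videos with a
bright mouse blob on a dark background, eyeblink sessions of eyelid traces,
metric cohorts with planted group effects, expression volumes with planted
dosage weights, paw placements, spike trains and grooming logs.  All
generators are fully deterministic given ``SynthConfig.seed``; independent
streams are derived with ``numpy.random.SeedSequence.spawn`` so adding one
generator never perturbs another.

Videos emulate the acquisition geometry of an overhead 50 frames/s camera:
each session opens with 185 mouse-free background frames of the empty
apparatus, followed by frames containing an anisotropic Gaussian intensity
blob centered on the true trajectory, plus additive pixel noise.  Distractor
blobs and dropped-blob frames are off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .tracking import ArenaGeometry, Trajectory, DETECTED

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "three_chamber_arena",
    "epm_arena",
    "ymaze_arena",
    "waypoint_trajectory",
    "random_trajectory",
    "make_arena_video",
    "make_eyeblink_session",
    "make_metric_groups",
    "make_expression_cohort",
    "make_paw_placements",
    "make_spike_train",
    "make_grooming_log",
    "write_frames",
    "read_frames",
    "TABLE_METRICS",
]

# Canonical behavioral-metric column names (task prefix + measure).
TABLE_METRICS = [
    "EPM_Commitment",
    "EPM_Distance",
    "EPM_Exploration Entrances",
    "EPM_Exploration Time",
    "EPM_Open-Arm Preference",
    "GR_Grooming Ratio",
    "SC_Baseline Distance",
    "SC_Novelty-Seeking",
    "SC_Social Preference",
    "SC_Test Distance",
    "YM_Final Learning",
    "YM_Initial Learning",
    "YM_Multisession Learning",
    "YM_Distance",
    "YM_Final Reversal 1",
    "YM_Initial Reversal 1",
    "YM_Multisession Reversal 1",
    "YM_Final Reversal 2",
    "YM_Initial Reversal 2",
    "EB_CR Probability",
]


@dataclass
class SynthConfig:
    """Study conditions for all generators.

    Video: 50 frames/s acquisition, a session opening with 185 mouse-free
    background frames.  Eyeblink: 200 paired + 20 CS-only + 10 US-only trials
    per session, 500 ms light CS, 30 ms airpuff US co-terminating with the CS.
    Expression: dominant-lobule labeled fraction ~ N(0.21, 0.12), spillover
    into the adjacent lobule ~ N(0.11, 0.11), matching targeted injections.
    """

    seed: int = 0
    # video
    frame_rate: float = 50.0
    frame_shape: tuple[int, int] = (240, 320)     # (h, w) px
    n_background_frames: int = 185
    video_noise_sd: float = 2.0                    # 8-bit intensity units
    blob_amplitude: float = 170.0
    blob_sigma: tuple[float, float] = (10.0, 6.0)  # (major, minor) px
    distractor_rate: float = 0.0                   # fraction of mouse frames
    distractor_scale: float = 1.4                  # distractor size multiplier
    dropout_rate: float = 0.0                      # dropped-blob frames
    # eyeblink
    eb_sample_rate: float = 1000.0                 # Hz
    eb_trial_dur_s: float = 1.0
    eb_cs_onset_s: float = 0.25
    eb_cs_dur_s: float = 0.5
    eb_us_dur_s: float = 0.03                      # co-terminates with CS
    eb_n_paired: int = 200
    eb_n_cs_only: int = 20
    eb_n_us_only: int = 10
    eb_cr_rate: float = 0.5                        # planted CR probability
    eb_cr_amp_range: tuple[float, float] = (0.35, 0.85)   # UR-fraction units
    eb_noncr_amp_range: tuple[float, float] = (0.0, 0.05)
    eb_cr_peak_latency_s: tuple[float, float] = (0.14, 0.24)  # after CS onset
    eb_noise_sd: float = 0.01                      # UR-fraction units
    eb_volts_per_ur: float = 2.0                   # raw-trace scale
    eb_baseline_volts: float = 0.3
    # metric cohorts
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 36, "perturbed": 12}
    )
    metric_names: list[str] = field(default_factory=lambda: list(TABLE_METRICS))
    movement_corr: float = 0.7                     # within movement block
    background_corr: float = 0.1
    effect_shift: np.ndarray | None = None         # per-metric SD units
    variance_inflation: np.ndarray | None = None   # per-metric SD multiplier
    # expression dosage
    volume_shape: tuple[int, int, int] = (40, 16, 24)  # (AP, DV, ML) voxels
    dominant_fraction: tuple[float, float] = (0.21, 0.12)  # mean, SD
    spillover_fraction: tuple[float, float] = (0.11, 0.11)
    dosage_weights: np.ndarray = field(
        default_factory=lambda: np.array([2.0, -1.5, 1.0, 0.0])
    )
    dosage_intercept: float = 0.5
    dosage_noise_sd: float = 0.1
    # gait walker
    stride_cm: float = 6.8
    fore_stance_cm: float = 1.8
    hind_stance_cm: float = 2.6
    n_steps: int = 8
    step_jitter_cm: float = 0.15
    gait_px_per_cm: float = 20.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Planted quantities the generators guarantee."""

    trajectory: Trajectory | None = None
    cr_labels: np.ndarray | None = None            # per counted trial, bool
    cr_amplitudes: np.ndarray | None = None
    group_means: dict[str, np.ndarray] | None = None
    dosage_weights: np.ndarray | None = None
    dosage_intercept: float | None = None
    lobule_fractions: np.ndarray | None = None     # mice x 4
    targeted_lobules: list[str] | None = None
    stride_cm: float | None = None
    stances_cm: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Arena factories
# ---------------------------------------------------------------------------

def three_chamber_arena(width_px: int = 316, height_px: int = 156,
                        apparatus_width_cm: float = 40.5) -> ArenaGeometry:
    """Three-chamber social apparatus: left/middle/right chambers + two cups."""
    px_per_cm = width_px / apparatus_width_cm
    w3 = width_px / 3
    rect = lambda x0, x1: [(x0, 0), (x1, 0), (x1, height_px), (x0, height_px)]
    cup_r = 0.5 * 10.5 * px_per_cm
    return ArenaGeometry(
        bounds=rect(0, width_px),
        zones={
            "mouse_chamber": rect(0, w3),
            "middle_chamber": rect(w3, 2 * w3),
            "object_chamber": rect(2 * w3, width_px),
        },
        px_per_cm=px_per_cm,
        cups={"mouse_cup": (w3 / 2, height_px / 2),
              "object_cup": (2.5 * w3, height_px / 2)},
        cup_radius_px=cup_r,
    )


def epm_arena(arm_len_px: int = 100, arm_w_px: int = 20,
              px_per_cm: float = 4.0) -> ArenaGeometry:
    """Plus maze: two open and two closed arms around a square center."""
    c = arm_len_px + arm_w_px / 2  # center of the maze
    h = arm_w_px / 2
    rect = lambda x0, y0, x1, y1: [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    size = 2 * arm_len_px + arm_w_px
    return ArenaGeometry(
        bounds=rect(0, 0, size, size),
        zones={
            "center": rect(c - h, c - h, c + h, c + h),
            "open_n": rect(c - h, 0, c + h, c - h),
            "open_s": rect(c - h, c + h, c + h, size),
            "closed_w": rect(0, c - h, c - h, c + h),
            "closed_e": rect(c + h, c - h, size, c + h),
        },
        px_per_cm=px_per_cm,
        arm_classes={"open_n": "open", "open_s": "open",
                     "closed_w": "closed", "closed_e": "closed"},
    )


def ymaze_arena(arm_len_px: int = 90, arm_w_px: int = 24,
                px_per_cm: float = 4.0) -> ArenaGeometry:
    """Y maze: start arm pointing down, left/right goal arms up at 120 deg."""
    cx, cy = 120.0, 110.0
    h = arm_w_px / 2

    def arm(angle_deg: float) -> list[tuple[float, float]]:
        a = np.deg2rad(angle_deg)
        d = np.array([np.cos(a), np.sin(a)])
        p = np.array([-d[1], d[0]]) * h
        base = np.array([cx, cy]) + d * h
        tip = np.array([cx, cy]) + d * (h + arm_len_px)
        return [tuple(base + p), tuple(tip + p), tuple(tip - p), tuple(base - p)]

    center = [(cx + h * np.cos(a), cy + h * np.sin(a))
              for a in np.deg2rad([90, 210, 330, 30, 150, 270])]
    return ArenaGeometry(
        bounds=[(0, 0), (240, 0), (240, 220), (0, 220)],
        zones={"center": center, "start_arm": arm(90),
               "left_arm": arm(210), "right_arm": arm(330)},
        px_per_cm=px_per_cm,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def waypoint_trajectory(points: list[tuple[float, float]], n_frames: int,
                        frame_rate: float, smooth_sigma: float = 0.0) -> Trajectory:
    """Deterministic path visiting ``points`` at constant speed.

    Useful for planting exact zone-entry sequences: linear interpolation
    between waypoints with optional Gaussian smoothing of the coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        pts = np.vstack([pts, pts])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1] if s[-1] > 0 else 1.0
    u = np.linspace(0, total, n_frames)
    x = np.interp(u, s, pts[:, 0])
    y = np.interp(u, s, pts[:, 1])
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter1d

        x = gaussian_filter1d(x, smooth_sigma)
        y = gaussian_filter1d(y, smooth_sigma)
    return Trajectory(
        t=np.arange(n_frames) / frame_rate, x=x, y=y,
        valid=np.full(n_frames, DETECTED, dtype=object), frame_rate=frame_rate,
    )


def random_trajectory(config: SynthConfig, arena: ArenaGeometry, n_frames: int,
                      margin_px: float = 18.0, speed_px_s: float = 60.0,
                      stream: int = 10) -> Trajectory:
    """Smooth random exploration of the arena interior.

    Random waypoints are drawn inside the bounds shrunk by ``margin_px`` (so
    the rendered blob stays fully in view) and interpolated at constant speed,
    then lightly smoothed.  Mean speed defaults to a leisurely walk.
    """
    rng = config.rng(stream)
    from shapely.geometry import Polygon

    inner = Polygon(arena.bounds).buffer(-margin_px)
    if inner.is_empty:
        raise ValueError("margin too large for arena")
    minx, miny, maxx, maxy = inner.bounds
    path_len = speed_px_s * n_frames / config.frame_rate
    pts = []
    start = inner.representative_point()
    pts.append((start.x, start.y))
    acc = 0.0
    while acc < path_len:
        from shapely.geometry import Point as _P

        while True:
            cand = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
            if inner.covers(_P(*cand)):
                break
        acc += float(np.hypot(cand[0] - pts[-1][0], cand[1] - pts[-1][1]))
        pts.append(cand)
    traj = waypoint_trajectory(pts, n_frames, config.frame_rate, smooth_sigma=5.0)
    for xi, yi in zip(traj.x, traj.y):
        if not arena.in_bounds(xi, yi):  # smoothing cannot escape a convex hull
            raise AssertionError("trajectory left arena bounds")
    return traj


# ---------------------------------------------------------------------------
# Arena video
# ---------------------------------------------------------------------------

def _render_blob(img: np.ndarray, cx: float, cy: float, amp: float,
                 sig_major: float, sig_minor: float, theta: float) -> None:
    h, w = img.shape
    r = int(np.ceil(3 * sig_major))
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    img[y0:y1, x0:x1] += amp * np.exp(
        -0.5 * ((u / sig_major) ** 2 + (v / sig_minor) ** 2)
    )


def _base_background(config: SynthConfig) -> np.ndarray:
    """Dim static scene: low base level with a gentle illumination gradient."""
    h, w = config.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    return 25.0 + 10.0 * (xx / max(w - 1, 1)) + 5.0 * (yy / max(h - 1, 1))


def make_arena_video(
    config: SynthConfig, truth_trajectory: Trajectory, arena: ArenaGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Render (background_frames, mouse_frames) as uint8 stacks.

    The background segment contains ``config.n_background_frames`` mouse-free
    frames of the empty apparatus.  Each mouse frame adds an anisotropic
    Gaussian blob at the true position, oriented along the direction of
    travel, plus additive Gaussian pixel noise.  Distractor blobs (placed far
    from the current position, larger than the mouse) and dropped-blob frames
    are inserted at the configured rates.
    """
    for xi, yi in zip(truth_trajectory.x, truth_trajectory.y):
        if not arena.in_bounds(xi, yi):
            raise ValueError("trajectory outside arena bounds")
    rng = config.rng(1)
    base = _base_background(config)
    h, w = config.frame_shape

    def finalize(img: np.ndarray) -> np.ndarray:
        noisy = img + rng.normal(0.0, config.video_noise_sd, img.shape)
        return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    bg_frames = np.stack(
        [finalize(base.copy()) for _ in range(config.n_background_frames)]
    )

    n = len(truth_trajectory)
    vx = np.gradient(truth_trajectory.x)
    vy = np.gradient(truth_trajectory.y)
    sig_a, sig_b = config.blob_sigma
    frames = []
    for i in range(n):
        img = base.copy()
        dropped = rng.random() < config.dropout_rate
        if not dropped:
            theta = float(np.arctan2(vy[i], vx[i])) if (vx[i] or vy[i]) else 0.0
            _render_blob(img, truth_trajectory.x[i], truth_trajectory.y[i],
                         config.blob_amplitude, sig_a, sig_b, theta)
        if i >= 10 and rng.random() < config.distractor_rate:
            # place the distractor well beyond the tracker's jump limit
            for _ in range(100):
                dx_, dy_ = rng.uniform(0, w), rng.uniform(0, h)
                d = np.hypot(dx_ - truth_trajectory.x[i], dy_ - truth_trajectory.y[i])
                if d > 130 and arena.in_bounds(dx_, dy_):
                    _render_blob(img, dx_, dy_, config.blob_amplitude,
                                 sig_a * config.distractor_scale,
                                 sig_b * config.distractor_scale, 0.0)
                    break
        frames.append(finalize(img))
    return bg_frames, np.stack(frames)


def write_frames(directory: str | Path, bg_frames: np.ndarray,
                 frames: np.ndarray, config: SynthConfig,
                 arena: ArenaGeometry) -> None:
    """Numbered 8-bit grayscale PNGs plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.concatenate([bg_frames, frames])
    for i, frame in enumerate(stack):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame)
    arena.to_json(directory / "arena.json")
    (directory / "video.json").write_text(json.dumps({
        "frame_rate": config.frame_rate,
        "n_background_frames": int(len(bg_frames)),
        "n_frames": int(len(stack)),
    }))


def read_frames(directory: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    directory = Path(directory)
    meta = json.loads((directory / "video.json").read_text())
    stack = np.stack([
        iio.imread(directory / f"frame_{i:06d}.png")
        for i in range(meta["n_frames"])
    ])
    nb = meta["n_background_frames"]
    return stack[:nb], stack[nb:], meta


# ---------------------------------------------------------------------------
# Eyeblink sessions
# ---------------------------------------------------------------------------

def _alpha_bump(t: np.ndarray, onset: float, tau: float, amp: float) -> np.ndarray:
    """Alpha-function transient peaking ``tau`` after ``onset`` at ``amp``."""
    rel = np.clip(t - onset, 0.0, None)
    return amp * (rel / tau) * np.exp(1.0 - rel / tau)


def make_eyeblink_session(config: SynthConfig):
    """One conditioning session with planted CR labels.

    Exactly ``eb_n_paired`` paired, ``eb_n_cs_only`` CS-only and
    ``eb_n_us_only`` US-only trials in randomized order.  Counted trials
    (paired + CS-only) carry a planted CR bump with probability
    ``eb_cr_rate``; CR amplitudes and latencies are drawn from the configured
    ranges, in fraction-of-full-UR units.  Returns
    ``(EyeblinkSession, GroundTruth)``.
    """
    from .eyeblink import EyeblinkSession

    rng = config.rng(2)
    types = (["paired"] * config.eb_n_paired
             + ["cs_only"] * config.eb_n_cs_only
             + ["us_only"] * config.eb_n_us_only)
    order = rng.permutation(len(types))
    types = [types[i] for i in order]

    fs = config.eb_sample_rate
    n_samp = int(round(config.eb_trial_dur_s * fs))
    t = np.arange(n_samp) / fs
    cs = config.eb_cs_onset_s
    us_onset = cs + config.eb_cs_dur_s - config.eb_us_dur_s  # co-terminating
    tau_cr, tau_ur = 0.05, 0.04

    traces = np.empty((len(types), n_samp))
    labels, amps = [], []
    for k, typ in enumerate(types):
        trace = np.zeros(n_samp)
        amp = 0.0
        if typ in ("paired", "cs_only"):
            if rng.random() < config.eb_cr_rate:
                amp = rng.uniform(*config.eb_cr_amp_range)
            else:
                amp = rng.uniform(*config.eb_noncr_amp_range)
            latency = rng.uniform(*config.eb_cr_peak_latency_s)
            if amp > 0:
                trace += _alpha_bump(t, cs + latency - tau_cr, tau_cr, amp)
            labels.append(amp > 0.15)
            amps.append(amp)
        if typ in ("paired", "us_only"):
            trace += _alpha_bump(t, us_onset, tau_ur, 1.0)
        trace += rng.normal(0.0, config.eb_noise_sd, n_samp)
        # raw units: voltage-proportional eyelid position
        traces[k] = config.eb_baseline_volts + config.eb_volts_per_ur * trace

    session = EyeblinkSession(
        trial_types=np.array(types, dtype=object),
        cs_onset_s=np.where(
            np.array([ty != "us_only" for ty in types]), cs, np.nan
        ),
        traces=traces,
        sample_rate=fs,
        us_onset_s=us_onset,
    )
    truth = GroundTruth(cr_labels=np.array(labels), cr_amplitudes=np.array(amps))
    return session, truth


# ---------------------------------------------------------------------------
# Metric cohorts
# ---------------------------------------------------------------------------

MOVEMENT_METRICS = {
    "EPM_Distance", "SC_Baseline Distance", "SC_Test Distance", "YM_Distance",
}


def default_covariance(metric_names: list[str], movement_corr: float = 0.7,
                       background_corr: float = 0.1) -> np.ndarray:
    """Unit-variance covariance with a strongly correlated movement block.

    Distance/velocity measures co-vary strongly (control PC1 is dominated by
    distance measures); all other pairs share a weak background correlation.
    """
    p = len(metric_names)
    cov = np.full((p, p), background_corr)
    idx = [i for i, m in enumerate(metric_names) if m in MOVEMENT_METRICS]
    for i in idx:
        for j in idx:
            if i != j:
                cov[i, j] = movement_corr
    np.fill_diagonal(cov, 1.0)
    return cov


def make_metric_groups(config: SynthConfig, covariance: np.ndarray | None = None):
    """Cohort table: control MVN plus shifted/inflated experimental groups.

    The control group is multivariate normal with the given covariance
    (default: movement-block structure).  Each non-control group adds the
    planted per-metric mean shift (``effect_shift``, in SD units) and
    multiplies designated metrics' SD by ``variance_inflation``.  Returns
    ``(DataFrame, GroundTruth)``; the frame is wide (mouse, group, metrics).
    """
    names = config.metric_names
    p = len(names)
    if covariance is None:
        covariance = default_covariance(names, config.movement_corr,
                                        config.background_corr)
    # reject non-positive-definite covariances up front
    eigmin = np.linalg.eigvalsh(covariance).min()
    if eigmin <= 0:
        raise ValueError("covariance is not positive definite")
    chol = np.linalg.cholesky(covariance)

    shift = (np.zeros(p) if config.effect_shift is None
             else np.asarray(config.effect_shift, dtype=float))
    inflation = (np.ones(p) if config.variance_inflation is None
                 else np.asarray(config.variance_inflation, dtype=float))
    if shift.shape != (p,) or inflation.shape != (p,):
        raise ValueError("effect vectors must match the metric count")

    rng = config.rng(3)
    rows = []
    means: dict[str, np.ndarray] = {}
    for group, n in config.group_sizes.items():
        if n < 3:
            raise ValueError("group sizes must be >= 3")
        z = rng.standard_normal((n, p)) @ chol.T
        if group != "control":
            z = z * inflation + shift
            means[group] = shift
        else:
            means[group] = np.zeros(p)
        for i in range(n):
            rows.append({"mouse": f"{group}_{i:02d}", "group": group,
                         **dict(zip(names, z[i]))})
    df = pd.DataFrame(rows)
    return df, GroundTruth(group_means=means)


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------

LOBULES = ["lobule_vi", "lobule_vii", "crus_i", "crus_ii"]


def _lobule_masks(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Four disjoint anterior-posterior slabs as lobule masks."""
    n_ap = shape[0]
    edges = np.linspace(0, n_ap, 5).astype(int)
    masks = {}
    for k, name in enumerate(LOBULES):
        m = np.zeros(shape, dtype=bool)
        m[edges[k]:edges[k + 1]] = True
        masks[name] = m
    return masks


def make_expression_cohort(config: SynthConfig, n_mice: int = 20,
                           metric_name: str = "YM_Multisession Reversal 1"):
    """Per-mouse binary volumes plus a dosage-linked metric table.

    Each mouse receives a targeted injection: the dominant lobule's labeled
    fraction is drawn from N(0.21, 0.12), spillover into an adjacent lobule
    from N(0.11, 0.11) (both clipped to sensible ranges), and trace label
    elsewhere.  The behavioral metric is the planted linear model
    ``intercept + weights . fractions + Gaussian noise``.  Returns
    ``(volumes, metrics DataFrame, GroundTruth)`` where ``volumes`` is a list
    of :class:`phenotrack.dosage.ExpressionVolume`.
    """
    from .dosage import ExpressionVolume

    rng = config.rng(4)
    masks = _lobule_masks(config.volume_shape)
    mask_sizes = {n: int(m.sum()) for n, m in masks.items()}

    volumes, fractions, targets = [], [], []
    for i in range(n_mice):
        target = LOBULES[i % 4]
        neighbor = LOBULES[(i % 4 + 1) % 4]
        fr = {n: rng.uniform(0.0, 0.02) for n in LOBULES}
        fr[target] = float(np.clip(rng.normal(*config.dominant_fraction), 0.02, 0.8))
        fr[neighbor] = float(np.clip(rng.normal(*config.spillover_fraction), 0.0, 0.6))
        label = np.zeros(config.volume_shape, dtype=bool)
        realized = []
        for name in LOBULES:
            size = mask_sizes[name]
            k = int(round(fr[name] * size))
            if k > 0:
                flat_idx = np.flatnonzero(masks[name])
                chosen = rng.choice(flat_idx, size=k, replace=False)
                label.flat[chosen] = True
            realized.append(k / size)
        volumes.append(ExpressionVolume(label=label, masks=dict(masks)))
        fractions.append(realized)
        targets.append(target)

    fractions_arr = np.array(fractions)
    w = np.asarray(config.dosage_weights, dtype=float)
    y = (config.dosage_intercept + fractions_arr @ w
         + rng.normal(0.0, config.dosage_noise_sd, n_mice))
    metrics = pd.DataFrame({
        "mouse": [f"inj_{i:02d}" for i in range(n_mice)],
        "group": [f"{t}_developmental" for t in targets],
        metric_name: y,
    })
    truth = GroundTruth(
        dosage_weights=w, dosage_intercept=config.dosage_intercept,
        lobule_fractions=fractions_arr, targeted_lobules=targets,
    )
    return volumes, metrics, truth


# ---------------------------------------------------------------------------
# Gait walker, spike trains, grooming logs
# ---------------------------------------------------------------------------

def make_paw_placements(config: SynthConfig, direction_deg: float = 0.0,
                        offset_cm: tuple[float, float] = (0.0, 0.0)):
    """Idealized straight-line walker with planted stride and stance.

    Paw placements advance by one stride per step along the walk direction;
    left/right paws sit half a stance width either side of the midline, with
    isotropic Gaussian placement jitter.  Returns
    ``(PawPlacements, GroundTruth)``.
    """
    from .gait import PawPlacements

    rng = config.rng(5)
    s, n = config.stride_cm, config.n_steps
    lateral = {"LF": config.fore_stance_cm / 2, "RF": -config.fore_stance_cm / 2,
               "LH": config.hind_stance_cm / 2, "RH": -config.hind_stance_cm / 2}
    phase = {"LF": 0.5, "RF": 0.0, "LH": 0.25, "RH": 0.75}  # within-cycle offsets
    a = np.deg2rad(direction_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    coords = {}
    for paw in ["LF", "RF", "LH", "RH"]:
        along = (np.arange(n) + phase[paw]) * s
        across = np.full(n, lateral[paw])
        pts_cm = np.column_stack([along, across])
        pts_cm += rng.normal(0.0, config.step_jitter_cm, pts_cm.shape)
        pts_cm = pts_cm @ rot.T + np.asarray(offset_cm)
        coords[paw] = pts_cm * config.gait_px_per_cm
    placements = PawPlacements(coords=coords, px_per_cm=config.gait_px_per_cm)
    truth = GroundTruth(stride_cm=s,
                        stances_cm=(config.fore_stance_cm, config.hind_stance_cm))
    return placements, truth


def make_spike_train(config: SynthConfig, kind: str = "poisson",
                     rate_hz: float = 60.0, n_spikes: int = 1000,
                     stream: int = 6) -> np.ndarray:
    """Spike times: ``regular`` (constant ISI) or ``poisson`` (exponential ISI)."""
    rng = config.rng(stream)
    if kind == "regular":
        # direct multiples keep ISIs exactly constant when 1/rate is dyadic
        return np.arange(n_spikes) * (1.0 / rate_hz)
    if kind == "poisson":
        isi = rng.exponential(1.0 / rate_hz, n_spikes - 1)
        return np.concatenate([[0.0], np.cumsum(isi)])
    raise ValueError(f"unknown train kind: {kind!r}")


def make_grooming_log(config: SynthConfig, n_events: int = 12,
                      condition: str = "saline", mean_bout_s: float = 3.0,
                      stream: int = 7):
    """Non-overlapping grooming events; some shorter than the 1 s filter."""
    from .metrics import GroomingLog

    rng = config.rng(stream)
    durations = rng.gamma(shape=1.5, scale=mean_bout_s / 1.5, size=n_events)
    gaps = rng.exponential(8.0, n_events)
    start = 0.0
    events = []
    for d, g in zip(durations, gaps):
        start += g
        events.append((start, start + d, condition))
        start += d
    return GroomingLog(events=events)
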