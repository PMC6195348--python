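"""Background-subtraction video tracking and zone/event extraction.

The tracker follows a classical single-animal pipeline: a Gaussian-filtered
mean background is subtracted from each Gaussian-filtered frame, the absolute
difference is thresholded, contours of the binary image are extracted, and
the largest-area contour is taken as the animal outline.  A candidate contour
is rejected when its centroid jumps more than ``jump_limit`` pixels from the
previous position, lies outside the arena bounds, or falls inside an
exclusion area; on rejection (or when no contour is found) the animal is
inferred to remain at its most recent detected location.

Coordinates are in pixels, origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon
from skimage.measure import find_contours

__all__ = [
    "Trajectory",
    "ArenaGeometry",
    "TrackerParams",
    "build_background",
    "track_frame",
    "track_video",
    "occupancy_and_entrances",
    "classify_epm_entries",
    "entry_commitment",
]

# Validity labels for per-frame positions.
DETECTED = "detected"
INFERRED = "inferred"
UNDEFINED = "undefined"  # before the first accepted contour


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered 2-D centroid positions with per-frame validity.

    ``valid`` holds ``"detected"``, ``"inferred"`` (position copied from the
    most recent detection) or ``"undefined"`` (no detection yet; x/y NaN).
    """

    t: np.ndarray          # seconds, strictly increasing at 1/frame_rate
    x: np.ndarray          # px
    y: np.ndarray          # px
    valid: np.ndarray      # str array
    frame_rate: float      # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=object)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("trajectory arrays must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time": self.t, "x": self.x, "y": self.y, "valid": self.valid}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: float) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            t=df["time"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            valid=df["valid"].to_numpy(dtype=object),
            frame_rate=frame_rate,
        )


@dataclass
class ArenaGeometry:
    """Named polygonal zones, arena bounds, exclusions and pixel scale.

    Zones are (name -> vertex list) polygons in pixel coordinates; ``cups``
    maps a cup name to its center, with interactions scored inside
    ``cup_radius_px + interaction_margin_cm * px_per_cm`` of that center.
    ``arm_classes`` tags elevated-plus-maze arm zones as open or closed.
    """

    bounds: list[tuple[float, float]]
    zones: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    exclusions: list[list[tuple[float, float]]] = field(default_factory=list)
    px_per_cm: float = 1.0
    cups: dict[str, tuple[float, float]] = field(default_factory=dict)
    cup_radius_px: float = 0.0
    interaction_margin_cm: float = 2.0
    arm_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        self._bounds_poly = Polygon(self.bounds)
        self._zone_polys = {n: Polygon(v) for n, v in self.zones.items()}
        self._excl_polys = [Polygon(v) for v in self.exclusions]

    # -- geometry queries ---------------------------------------------------

    def in_bounds(self, x: float, y: float) -> bool:
        return self._bounds_poly.covers(Point(x, y))

    def in_exclusion(self, x: float, y: float) -> bool:
        return any(p.covers(Point(x, y)) for p in self._excl_polys)

    def zone_of(self, x: float, y: float) -> str | None:
        """First zone (insertion order) covering the point, else None."""
        pt = Point(x, y)
        for name, poly in self._zone_polys.items():
            if poly.covers(pt):
                return name
        return None

    def zone_polygon(self, name: str) -> Polygon:
        return self._zone_polys[name]

    def near_cup(self, x: float, y: float, cup: str) -> bool:
        cx, cy = self.cups[cup]
        radius = self.cup_radius_px + self.interaction_margin_cm * self.px_per_cm
        return (x - cx) ** 2 + (y - cy) ** 2 <= radius**2

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bounds": self.bounds,
            "zones": self.zones,
            "exclusions": self.exclusions,
            "px_per_cm": self.px_per_cm,
            "cups": self.cups,
            "cup_radius_px": self.cup_radius_px,
            "interaction_margin_cm": self.interaction_margin_cm,
            "arm_classes": self.arm_classes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArenaGeometry":
        d = json.loads(Path(path).read_text())
        return cls(
            bounds=[tuple(p) for p in d["bounds"]],
            zones={k: [tuple(p) for p in v] for k, v in d["zones"].items()},
            exclusions=[[tuple(p) for p in poly] for poly in d["exclusions"]],
            px_per_cm=d["px_per_cm"],
            cups={k: tuple(v) for k, v in d["cups"].items()},
            cup_radius_px=d["cup_radius_px"],
            interaction_margin_cm=d["interaction_margin_cm"],
            arm_classes=d["arm_classes"],
        )


@dataclass
class TrackerParams:
    """Tunables of the background-subtraction tracker.

    ``threshold`` is the user-defined cut on the absolute difference image
    (8-bit intensity units).  ``jump_limit`` rejects contours whose center
    moved more than this many pixels between consecutive frames.
    """

    threshold: float = 25.0
    sigma: float = 2.0            # Gaussian pre-filter, px
    jump_limit: float = 100.0     # px
    background_frames: int = 185

    def __post_init__(self) -> None:
        if self.jump_limit <= 0:
            raise ValueError("jump_limit must be positive")


# ---------------------------------------------------------------------------
# Tracker
# ---------------------------------------------------------------------------

def build_background(frames: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Gaussian-filtered pixel-wise mean of a mouse-free frame stack."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need a non-empty (n, h, w) frame stack")
    return gaussian_filter(frames.mean(axis=0), sigma=sigma)


def _polygon_area_centroid(contour: np.ndarray) -> tuple[float, float, float]:
    """Shoelace area and centroid of a closed (row, col) contour."""
    # find_contours yields (row, col); convert to (x, y) = (col, row)
    x = contour[:, 1]
    y = contour[:, 0]
    cross = x[:-1] * y[1:] - x[1:] * y[:-1]
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return 0.0, float(x.mean()), float(y.mean())
    cx = ((x[:-1] + x[1:]) * cross).sum() / (6.0 * area)
    cy = ((y[:-1] + y[1:]) * cross).sum() / (6.0 * area)
    return abs(area), float(cx), float(cy)


def _candidate_contours(
    frame: np.ndarray, background: np.ndarray, params: TrackerParams
) -> list[tuple[float, float, float]]:
    """(area, cx, cy) for each closed contour of the thresholded difference."""
    diff = np.abs(gaussian_filter(np.asarray(frame, dtype=float), params.sigma) - background)
    binary = (diff > params.threshold).astype(float)
    # pad so blobs touching the frame edge still yield closed contours
    padded = np.pad(binary, 1, mode="constant")
    out = []
    for contour in find_contours(padded, 0.5):
        area, cx, cy = _polygon_area_centroid(contour)
        if area > 0:
            out.append((area, cx - 1.0, cy - 1.0))
    return out


def track_frame(
    frame: np.ndarray,
    background: np.ndarray,
    params: TrackerParams,
    previous: tuple[float, float] | None,
    arena: ArenaGeometry,
) -> tuple[tuple[float, float] | None, str]:
    """Locate the animal in one frame.

    Returns ``((x, y), validity)``.  The largest-area acceptable contour wins;
    contours are rejected for jumping beyond ``params.jump_limit`` from
    ``previous`` (rule suspended when no previous position exists), for lying
    outside the arena bounds, or inside an exclusion area.  With no acceptable
    contour the previous position is returned flagged ``"inferred"``; with no
    previous position either, ``(None, "undefined")``.
    """
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    candidates = _candidate_contours(frame, background, params)

    def acceptable(cx: float, cy: float) -> bool:
        if not arena.in_bounds(cx, cy):
            return False
        if arena.in_exclusion(cx, cy):
            return False
        if previous is not None:
            if np.hypot(cx - previous[0], cy - previous[1]) > params.jump_limit:
                return False
        return True

    accepted = [(a, cx, cy) for a, cx, cy in candidates if acceptable(cx, cy)]
    if accepted:
        best_area = max(a for a, _, _ in accepted)
        ties = [(cx, cy) for a, cx, cy in accepted if a == best_area]
        if len(ties) > 1 and previous is not None:
            # equal-area tie: nearest to the previous position
            ties.sort(key=lambda p: np.hypot(p[0] - previous[0], p[1] - previous[1]))
        return ties[0], DETECTED
    if previous is not None:
        return previous, INFERRED
    return None, UNDEFINED


def track_video(
    frames: np.ndarray,
    background: np.ndarray,
    params: TrackerParams,
    arena: ArenaGeometry,
    frame_rate: float,
) -> Trajectory:
    """Track a full session; output length always equals the frame count."""
    previous: tuple[float, float] | None = None
    xs, ys, vs = [], [], []
    for frame in frames:
        pos, validity = track_frame(frame, background, params, previous, arena)
        if pos is None:
            xs.append(np.nan)
            ys.append(np.nan)
        else:
            xs.append(pos[0])
            ys.append(pos[1])
            previous = pos if validity == DETECTED else previous
        vs.append(validity)
    t = np.arange(len(frames)) / frame_rate
    return Trajectory(t=t, x=np.array(xs), y=np.array(ys),
                      valid=np.array(vs, dtype=object), frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# Zone occupancy, entrances, distance
# ---------------------------------------------------------------------------

def zone_labels(traj: Trajectory, arena: ArenaGeometry) -> list[str | None]:
    """Per-frame zone label (None when out of every zone or undefined)."""
    labels: list[str | None] = []
    for x, y, v in zip(traj.x, traj.y, traj.valid):
        if v == UNDEFINED or not np.isfinite(x):
            labels.append(None)
        else:
            labels.append(arena.zone_of(x, y))
    return labels


def occupancy_and_entrances(
    traj: Trajectory, arena: ArenaGeometry
) -> dict:
    """Per-zone time and entrance counts, transitions, distance and velocity.

    Time in a zone is the number of frames the animal occupies it divided by
    the frame rate; an entrance is a transition of the zone label into the
    zone; distance is the summed Euclidean step length in cm.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    labels = zone_labels(traj, arena)
    names = list(arena.zones)
    time_s = {n: labels.count(n) / traj.frame_rate for n in names}
    out_of_zone_s = labels.count(None) / traj.frame_rate

    entrances = {n: 0 for n in names}
    transitions = []  # (time s, from, to); session start counts as an entry
    if labels and labels[0] is not None:
        entrances[labels[0]] += 1
        transitions.append((traj.t[0], None, labels[0]))
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            transitions.append((traj.t[i], labels[i - 1], labels[i]))
            if labels[i] is not None:
                entrances[labels[i]] += 1

    pos = traj.positions
    ok = np.isfinite(pos).all(axis=1)
    steps = np.linalg.norm(np.diff(pos[ok], axis=0), axis=1) if ok.sum() > 1 else np.array([])
    distance_cm = float(steps.sum()) / arena.px_per_cm
    duration_s = len(traj) / traj.frame_rate
    return {
        "time_s": time_s,
        "out_of_zone_s": out_of_zone_s,
        "entrances": entrances,
        "transitions": transitions,
        "distance_cm": distance_cm,
        "mean_velocity_cm_s": distance_cm / duration_s,
        "duration_s": duration_s,
    }


def cup_interaction_times(traj: Trajectory, arena: ArenaGeometry) -> dict[str, float]:
    """Seconds spent with the centroid inside each cup's interaction annulus."""
    out = {}
    for cup in arena.cups:
        n = sum(
            1
            for x, y, v in zip(traj.x, traj.y, traj.valid)
            if v != UNDEFINED and np.isfinite(x) and arena.near_cup(x, y, cup)
        )
        out[cup] = n / traj.frame_rate
    return out


def transitions_to_csv(result: dict, path: str | Path) -> None:
    pd.DataFrame(
        result["transitions"], columns=["time", "from_zone", "to_zone"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Elevated plus-maze entry classification
# ---------------------------------------------------------------------------

def classify_epm_entries(
    traj: Trajectory,
    arena: ArenaGeometry,
    full_depth_cm: float = 4.0,
) -> dict[str, dict[str, int]]:
    """Split arm entries into full and jittery by penetration depth.

    An excursion into an arm that reaches at least ``full_depth_cm`` from the
    arm's entrance border (the border with the central zone, measured as the
    distance from the center polygon) counts as a full entry; an excursion
    that enters but never reaches that depth is jittery.  Returns
    ``{"open": {"full": ..., "jittery": ...}, "closed": {...}}``.
    """
    labels = zone_labels(traj, arena)
    center_poly = arena.zone_polygon("center") if "center" in arena.zones else None
    depth_px = full_depth_cm * arena.px_per_cm
    counts = {"open": {"full": 0, "jittery": 0}, "closed": {"full": 0, "jittery": 0}}

    i = 0
    n = len(labels)
    while i < n:
        lab = labels[i]
        if lab in arena.arm_classes:
            arm_class = arena.arm_classes[lab]
            j = i
            max_depth = 0.0
            while j < n and labels[j] == lab:
                pt = Point(traj.x[j], traj.y[j])
                if center_poly is not None:
                    depth = center_poly.distance(pt)
                else:
                    depth = 0.0
                max_depth = max(max_depth, depth)
                j += 1
            kind = "full" if max_depth >= depth_px else "jittery"
            counts[arm_class][kind] += 1
            i = j
        else:
            i += 1
    return counts


def entry_commitment(full: int, jittery: int) -> float:
    """Full entries over full-plus-jittery entries (NaN when both zero)."""
    total = full + jittery
    return np.nan if total == 0 else full / total
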