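"""Stride length and stance width from manually annotated paw placements.

Each paw's placements are the (x, y) pixel coordinates at which it touched
the walking surface, ordered by step.  Stride length is the mean Euclidean
distance between successive placements of the same paw.  Stance width is the
mean left-right paw separation within a girdle (fore: LF-RF, hind: LH-RH),
projected perpendicular to the locomotion axis — the principal axis of all
placements — so that forward stagger between paired steps does not inflate
the width.  Both are reported in cm via the ruler-derived pixel scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PawPlacements", "stride_lengths", "stances"]

PAWS = ("LF", "RF", "LH", "RH")


@dataclass
class PawPlacements:
    """Ordered placement coordinates per paw, plus the pixel-to-cm scale."""

    coords: dict[str, np.ndarray]   # paw -> (n, 2) px
    px_per_cm: float

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        self.coords = {p: np.asarray(c, dtype=float).reshape(-1, 2)
                       for p, c in self.coords.items()}

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"paw": paw, "step_index": i, "x": x, "y": y}
            for paw, pts in self.coords.items()
            for i, (x, y) in enumerate(pts)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, px_per_cm: float) -> "PawPlacements":
        df = pd.read_csv(path).sort_values(["paw", "step_index"])
        coords = {
            paw: g[["x", "y"]].to_numpy()
            for paw, g in df.groupby("paw", sort=False)
        }
        return cls(coords=coords, px_per_cm=px_per_cm)


def stride_lengths(p: PawPlacements) -> dict[str, float]:
    """Mean distance between successive placements of each paw, in cm.

    A paw with fewer than two placements is reported NaN.
    """
    out = {}
    for paw in PAWS:
        pts = p.coords.get(paw)
        if pts is None or len(pts) < 2:
            out[paw] = np.nan
            continue
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        out[paw] = float(steps.mean()) / p.px_per_cm
    return out


def _locomotion_axis(p: PawPlacements) -> np.ndarray:
    """Unit vector along the principal axis of all placements."""
    pts = np.vstack([c for c in p.coords.values() if len(c)])
    centered = pts - pts.mean(axis=0)
    # dominant right singular vector = direction of largest spread
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def stances(p: PawPlacements) -> tuple[float, float]:
    """(fore stance cm, hind stance cm): mean left-right separation.

    Left and right placements of a girdle are paired by step index after
    trimming to the common length; each pair's separation is projected
    perpendicular to the locomotion axis.  A girdle missing a paw (or with
    no complete pair) is NaN.
    """
    axis = _locomotion_axis(p)
    perp = np.array([-axis[1], axis[0]])

    def girdle(left: str, right: str) -> float:
        a, b = p.coords.get(left), p.coords.get(right)
        if a is None or b is None:
            return np.nan
        n = min(len(a), len(b))
        if n == 0:
            return np.nan
        sep = a[:n] - b[:n]
        return float(np.abs(sep @ perp).mean()) / p.px_per_cm

    return girdle("LF", "RF"), girdle("LH", "RH")
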