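"""Per-lobule expression quantification and linear dosage models.

Chemogenetic receptor expression is quantified per mouse as the fraction of
each cerebellar lobule's voxels carrying reporter label (lobule VI, lobule
VII, crus I, crus II).  For each continuous behavioral metric, an ordinary
least-squares model predicts the metric from the four fractions plus an
intercept; the normalized weight of a lobule is its coefficient divided by
its standard error, so |weight| ~ 2 marks a conventionally significant
dosage dependence.  Models are fitted per cohort on injected mice only —
uninjected controls have no expression and carry no dosage information.

Volumes arrive on a common isotropic grid with axis order
(anterior-posterior, dorsoventral, mediolateral); atlas registration is out
of scope here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ExpressionVolume",
    "DosageFit",
    "TracingCounts",
    "lobule_fractions",
    "classify_majority_lobule",
    "expression_vector",
    "fit_dosage_models",
    "relative_expression",
    "LOBULE_ORDER",
    "DISCRETE_METRICS",
    "TRACING_REGIONS",
]

LOBULE_ORDER = ["lobule_vi", "lobule_vii", "crus_i", "crus_ii"]

# Discrete Y-maze metrics excluded from the continuous-metric dosage models.
DISCRETE_METRICS = frozenset({
    "YM_Final Learning", "YM_Initial Reversal 2", "YM_Final Reversal 2",
})

TRACING_REGIONS = [
    "motor", "somatosensory", "prelimbic", "orbitofrontal",
    "anterior_cingulate", "infralimbic", "visual", "parietal_association",
    "retrosplenial", "agranular_insular",
]


@dataclass
class ExpressionVolume:
    """Binary labeled-voxel array with four disjoint lobule masks."""

    label: np.ndarray               # bool, (AP, DV, ML)
    masks: dict[str, np.ndarray]    # lobule name -> bool array, same shape

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=bool)
        overlap = np.zeros(self.label.shape, dtype=int)
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.label.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            self.masks[name] = m
            overlap += m
        if np.any(overlap > 1):
            raise ValueError("lobule masks must be pairwise disjoint")

    # -- I/O: dense arrays + JSON manifest ----------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "label.npy", self.label)
        for name, m in self.masks.items():
            np.save(directory / f"mask_{name}.npy", m)
        (directory / "manifest.json").write_text(json.dumps({
            "shape": list(self.label.shape),
            "axis_order": ["anterior_posterior", "dorsoventral", "mediolateral"],
            "masks": list(self.masks),
        }))

    @classmethod
    def load(cls, directory: str | Path) -> "ExpressionVolume":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        label = np.load(directory / "label.npy")
        masks = {n: np.load(directory / f"mask_{n}.npy")
                 for n in manifest["masks"]}
        return cls(label=label, masks=masks)


@dataclass
class DosageFit:
    """OLS dosage model for one behavioral metric."""

    metric: str
    intercept: float
    coefficients: np.ndarray        # per lobule, LOBULE_ORDER
    std_errors: np.ndarray
    normalized_weights: np.ndarray  # coefficient / SE
    n_mice: int
    r_squared: float


@dataclass
class TracingCounts:
    """GFP-positive section counts per neocortical region."""

    counts: dict[str, float]

    def __post_init__(self) -> None:
        for region, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {region!r}")


# ---------------------------------------------------------------------------
# Expression quantification
# ---------------------------------------------------------------------------

def lobule_fractions(v: ExpressionVolume,
                     order: list[str] | None = None) -> np.ndarray:
    """Fraction of each lobule's voxels carrying label, in [0, 1]^4."""
    order = order or LOBULE_ORDER
    out = np.empty(len(order))
    for i, name in enumerate(order):
        mask = v.masks[name]
        size = int(mask.sum())
        if size == 0:
            raise ValueError(f"empty mask for lobule {name!r}")
        out[i] = np.count_nonzero(v.label & mask) / size
    return out


def classify_majority_lobule(fractions: np.ndarray,
                             order: list[str] | None = None,
                             ) -> tuple[str | None, bool]:
    """(lobule with the largest labeled fraction, tie flag).

    Ties go to the earlier lobule in the fixed order and are flagged; an
    all-zero vector is unclassified (None).
    """
    order = order or LOBULE_ORDER
    fr = np.asarray(fractions, dtype=float)
    if np.all(fr == 0):
        return None, False
    best = int(np.argmax(fr))
    tie = bool(np.sum(fr == fr[best]) > 1)
    return order[best], tie


def expression_vector(v: ExpressionVolume,
                      roi_mask: np.ndarray | None = None) -> np.ndarray:
    """Mediolateral expression profile of a labeled volume.

    The (optionally ROI-masked) binary volume is max-projected along the
    anterior-posterior axis, then averaged over the dorsoventral axis at
    each mediolateral coordinate.
    """
    label = v.label
    if roi_mask is not None:
        label = label & np.asarray(roi_mask, dtype=bool)
    projected = label.max(axis=0)       # (DV, ML)
    return projected.mean(axis=0)       # (ML,)


# ---------------------------------------------------------------------------
# Linear dosage models
# ---------------------------------------------------------------------------

def fit_dosage_models(metrics: pd.DataFrame, fractions: np.ndarray,
                      min_mice: int = 6) -> dict[str, DosageFit]:
    """One OLS model per continuous metric: metric ~ intercept + fractions.

    ``metrics`` holds injected mice only (one row per mouse, metric columns);
    ``fractions`` is the aligned (n_mice, 4) per-lobule expression matrix.
    Discrete Y-maze metrics are skipped; a metric needs at least ``min_mice``
    non-missing mice.  The normalized weight is coefficient / SE with the
    standard OLS covariance at n - 5 residual degrees of freedom.  A
    rank-deficient design raises, naming the collinear lobules.
    """
    fractions = np.asarray(fractions, dtype=float)
    metric_cols = [c for c in metrics.columns if c not in ("mouse", "group")]
    if fractions.shape != (len(metrics), len(LOBULE_ORDER)):
        raise ValueError("fractions must be (n_mice, 4) aligned to the table")

    fits: dict[str, DosageFit] = {}
    for metric in metric_cols:
        if metric in DISCRETE_METRICS:
            continue
        y = metrics[metric].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < min_mice:
            continue
        x = sm.add_constant(fractions[ok], has_constant="add")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            collinear = _collinear_lobules(fractions[ok])
            raise ValueError(
                f"rank-deficient design for {metric!r}; collinear lobules: {collinear}"
            )
        res = sm.OLS(y[ok], x).fit()
        coefs = res.params[1:]
        ses = res.bse[1:]
        fits[metric] = DosageFit(
            metric=metric,
            intercept=float(res.params[0]),
            coefficients=np.asarray(coefs),
            std_errors=np.asarray(ses),
            normalized_weights=np.asarray(coefs) / np.asarray(ses),
            n_mice=int(ok.sum()),
            r_squared=float(res.rsquared),
        )
    return fits


def _collinear_lobules(fractions: np.ndarray) -> list[str]:
    """Lobules whose column is in the span of the others (for error messages)."""
    names = []
    n = fractions.shape[1]
    full_rank = np.linalg.matrix_rank(fractions)
    for j in range(n):
        others = np.delete(fractions, j, axis=1)
        if np.linalg.matrix_rank(others) == full_rank:
            names.append(LOBULE_ORDER[j])
    return names or list(LOBULE_ORDER)


def fits_to_frame(fits: dict[str, DosageFit]) -> pd.DataFrame:
    rows = []
    for f in fits.values():
        row = {"metric": f.metric, "intercept": f.intercept,
               "n_mice": f.n_mice, "r_squared": f.r_squared}
        for i, lob in enumerate(LOBULE_ORDER):
            row[f"coef_{lob}"] = f.coefficients[i]
            row[f"se_{lob}"] = f.std_errors[i]
            row[f"weight_{lob}"] = f.normalized_weights[i]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Long-distance tracing
# ---------------------------------------------------------------------------

def relative_expression(c: TracingCounts,
                        reference: str = "motor") -> dict[str, float]:
    """Each region's section count divided by the reference (motor) count.

    The reference region's own ratio is identically 1 for any positive count.
    """
    if reference not in c.counts:
        raise ValueError(f"missing reference region {reference!r}")
    ref = c.counts[reference]
    if ref <= 0:
        raise ValueError("reference-region count must be positive")
    return {region: count / ref for region, count in c.counts.items()}
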