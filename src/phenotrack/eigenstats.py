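"""Control-space PCA ("eigenbehaviors") and the battery's multivariate tests.

The eigenbehavior analysis asks whether a perturbed group differs from
controls along concerted combinations of behavioral metrics rather than any
single one.  Controls are z-scored by their own mean and SD, a PCA is fitted
on the z-scored control matrix, and every group (controls included) is
projected onto the resulting orthonormal loading basis after the SAME
control-referenced z-scoring.  A component is flagged high-contribution for
a group when all three hold: |mean score difference from controls| >= 0.01
(in component-score units), the component carries >= 10% of the group's
total projected variance, and a two-sample two-tailed t-test against the
control scores gives p < 0.05.

Also here: variance-ratio F-tests, pooled-SD Cohen's d, two-sample KS
comparison, and Spearman correlation networks with exact-permutation
p-values (exhaustive for n <= 9, seeded Monte-Carlo above that).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EigenSpace",
    "GroupProjection",
    "fit_control_space",
    "project_group",
    "high_contribution_pcs",
    "variance_ratio_test",
    "cohens_d",
    "spearman_permutation",
    "correlation_network",
    "ks_compare",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Eigenbehavior space
# ---------------------------------------------------------------------------

@dataclass
class EigenSpace:
    """Control normalization plus the orthonormal component basis."""

    metric_names: list[str]
    mean: np.ndarray                # control mean per metric
    sd: np.ndarray                  # control SD per metric (ddof=1)
    components: np.ndarray          # (k, p) unit-norm loadings, variance-ordered
    control_variance: np.ndarray    # (k,) control score variance per component

    def zscore(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.components, columns=self.metric_names,
            index=[f"PC{i + 1}" for i in range(len(self.components))],
        )


@dataclass
class GroupProjection:
    """A group's coordinates in the control eigenbehavior space."""

    scores: np.ndarray              # (n, k)
    variance_fraction: np.ndarray   # (k,) sums to 1 over retained components
    mean_diff: np.ndarray           # (k,) mean score minus control mean score


def _extract(matrix: pd.DataFrame | np.ndarray,
             metric_subset: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        names = metric_subset or [
            c for c in matrix.columns if c not in ("mouse", "group")
        ]
        missing = [n for n in names if n not in matrix.columns]
        if missing:
            raise ValueError(f"metrics absent from the table: {missing}")
        return matrix[names].to_numpy(dtype=float), list(names)
    arr = np.asarray(matrix, dtype=float)
    names = metric_subset or [f"m{i}" for i in range(arr.shape[1])]
    return arr, list(names)


def fit_control_space(controls: pd.DataFrame | np.ndarray,
                      metric_subset: list[str] | None = None) -> EigenSpace:
    """Z-score controls by their own mean/SD and fit a PCA on the result.

    Requires at least one more control mouse than metrics and no missing
    values in the subset (mice with a missing metric should be dropped by
    the caller before fitting).  Components are ordered by descending
    control variance; each loading's sign is fixed so its largest-magnitude
    entry is positive.
    """
    x, names = _extract(controls, metric_subset)
    n, p = x.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} control mice for {p} metrics, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing values in the control matrix")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance metric(s): {[names[i] for i in zero]}")
    z = (x - mean) / sd
    # z has exactly zero column means, so the SVD is the PCA
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    components = vt
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    control_variance = s**2 / (n - 1)
    return EigenSpace(metric_names=names, mean=mean, sd=sd,
                      components=components, control_variance=control_variance)


def project_group(group: pd.DataFrame | np.ndarray, space: EigenSpace,
                  control_scores: np.ndarray | None = None) -> GroupProjection:
    """Project a group onto the control space.

    Rows are z-scored with the CONTROL mean/SD, then multiplied by the
    loadings.  Variance fractions are each component's share of the group's
    total projected variance; mean differences are relative to the control
    score means (zero by construction when ``control_scores`` is omitted).
    """
    x, names = _extract(group, space.metric_names)
    if names != space.metric_names:
        raise ValueError("group metrics do not match the fitted space")
    scores = space.zscore(x) @ space.components.T
    var = scores.var(axis=0, ddof=1)
    total = var.sum()
    frac = var / total if total > 0 else np.full_like(var, np.nan)
    ctrl_mean = (np.zeros(scores.shape[1]) if control_scores is None
                 else control_scores.mean(axis=0))
    return GroupProjection(scores=scores, variance_fraction=frac,
                           mean_diff=scores.mean(axis=0) - ctrl_mean)


def high_contribution_pcs(gp: GroupProjection, control_scores: np.ndarray,
                          mean_diff_min: float = 0.01,
                          var_fraction_min: float = 0.10,
                          alpha: float = 0.05) -> list[int]:
    """Components meeting all three high-contribution criteria (0-based).

    A component qualifies when the group's mean score differs from controls
    by at least ``mean_diff_min`` in absolute value, carries at least
    ``var_fraction_min`` of the group's projected variance, and differs from
    the control scores at ``alpha`` by a two-sample two-tailed t-test.
    """
    if gp.scores.shape[0] < 2:
        raise ValueError("need at least 2 mice in the group")
    selected = []
    for k in range(gp.scores.shape[1]):
        if abs(gp.mean_diff[k]) < mean_diff_min:
            continue
        if gp.variance_fraction[k] < var_fraction_min:
            continue
        p = stats.ttest_ind(gp.scores[:, k], control_scores[:, k]).pvalue
        if p < alpha:
            selected.append(k)
    return selected


# ---------------------------------------------------------------------------
# Univariate group tests
# ---------------------------------------------------------------------------

def variance_ratio_test(group: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test of variance ratio, group over control.

    F = s2_group / s2_control with (n_g - 1, n_c - 1) degrees of freedom;
    the two-sided p doubles the smaller tail.
    """
    g = np.asarray(group, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(g) < 2 or len(c) < 2:
        raise ValueError("need n >= 2 in each sample")
    s2c = c.var(ddof=1)
    if s2c == 0:
        raise ValueError("zero control variance")
    f = g.var(ddof=1) / s2c
    dist = stats.f(len(g) - 1, len(c) - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean_a - mean_b) / pooled SD, pooled with n_a + n_b - 2 df.

    NaN when the pooled SD is zero (both samples constant).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each sample")
    na, nb = len(a), len(b)
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def ks_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and p-value."""
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Spearman correlation with permutation p-values
# ---------------------------------------------------------------------------

_PERM_CACHE: dict[int, np.ndarray] = {}


def _all_permutations(n: int) -> np.ndarray:
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(itertools.permutations(range(n))))
    return _PERM_CACHE[n]


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def spearman_permutation(x: np.ndarray, y: np.ndarray,
                         exact_max_n: int = 9, n_mc: int = 100_000,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[float, float]:
    """Spearman rho with a two-sided permutation p-value.

    For n <= ``exact_max_n`` the null distribution is the exhaustive set of
    n! label permutations; above that, ``n_mc`` seeded Monte-Carlo draws with
    the add-one estimator p = (1 + #extreme) / (1 + n_mc).  The permutation
    scheme preserves any tie structure (ranks are permuted whole).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("need paired samples with n >= 4")
    rx, ry = _rank(x), _rank(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    if denom == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho = float(rxc @ ryc / denom)

    if n <= exact_max_n:
        perms = _all_permutations(n)
        rho_null = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        hits = 0
        block = 10_000
        done = 0
        while done < n_mc:
            m = min(block, n_mc - done)
            idx = np.argsort(rng.random((m, n)), axis=1)
            rho_null = (ryc[idx] @ rxc) / denom
            hits += int(np.sum(np.abs(rho_null) >= abs(rho) - 1e-12))
            done += m
        p = (1 + hits) / (1 + n_mc)
    return rho, p


def correlation_network(matrix: pd.DataFrame, alpha: float = 0.01,
                        method: str = "permutation",
                        exact_max_n: int = 9, n_mc: int = 100_000,
                        seed: int = 0, keep_all: bool = False) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations between all metric pairs.

    ``method`` selects the p-value: ``"permutation"`` (exact for n <= 9,
    Monte-Carlo otherwise) or ``"t"`` (the large-sample t approximation).
    Pairs with fewer than 4 complete observations, or a constant metric, are
    skipped and logged.  Returns the edges with p < ``alpha`` (all computed
    pairs when ``keep_all``) as columns (metric_a, metric_b, rho, p, n).
    """
    names = [c for c in matrix.columns if c not in ("mouse", "group")]
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(names, 2):
        pair = matrix[[a, b]].dropna()
        if len(pair) < 4:
            logger.info("skipping %s~%s: only %d complete pairs", a, b, len(pair))
            continue
        xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            logger.info("skipping %s~%s: constant metric", a, b)
            continue
        if method == "permutation":
            rho, p = spearman_permutation(xa, xb, exact_max_n=exact_max_n,
                                          n_mc=n_mc, rng=rng)
        elif method == "t":
            res = stats.spearmanr(xa, xb)
            rho, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"metric_a": a, "metric_b": b, "rho": rho, "p": p,
                     "n": len(pair)})
    edges = pd.DataFrame(rows, columns=["metric_a", "metric_b", "rho", "p", "n"])
    if keep_all:
        return edges
    return edges[edges["p"] < alpha].reset_index(drop=True)
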