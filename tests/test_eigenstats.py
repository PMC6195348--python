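"""Eigenbehavior PCA, group tests and permutation correlation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenotrack.eigenstats import (
    cohens_d,
    correlation_network,
    fit_control_space,
    high_contribution_pcs,
    ks_compare,
    project_group,
    spearman_permutation,
    variance_ratio_test,
)


@pytest.fixture
def control_matrix(rng):
    cov = np.full((6, 6), 0.3)
    np.fill_diagonal(cov, 1.0)
    return rng.standard_normal((30, 6)) @ np.linalg.cholesky(cov).T


class TestControlSpace:
    def test_control_scores_centered(self, control_matrix):
        space = fit_control_space(control_matrix)
        gp = project_group(control_matrix, space)
        assert np.abs(gp.scores.mean(axis=0)).max() < 1e-12

    def test_variance_conserved(self, control_matrix):
        space = fit_control_space(control_matrix)
        z = space.zscore(control_matrix)
        total = z.var(axis=0, ddof=1).sum()
        assert space.control_variance.sum() == pytest.approx(total)

    def test_perfectly_correlated_pair_gives_one_component(self):
        x = np.linspace(0, 1, 10)
        mat = np.column_stack([x, 2 * x + 1])  # correlation exactly 1
        space = fit_control_space(mat)
        frac = space.control_variance / space.control_variance.sum()
        assert frac[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, control_matrix):
        space = fit_control_space(control_matrix)
        gram = space.components @ space.components.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-10)

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_control_space(rng.standard_normal((6, 6)))

    def test_zero_variance_metric_named(self, rng):
        x = rng.standard_normal((10, 3))
        x[:, 1] = 5.0
        with pytest.raises(ValueError, match="m1"):
            fit_control_space(x)


class TestProjection:
    def test_self_projection_reproduces_variance_ratios(self, control_matrix):
        space = fit_control_space(control_matrix)
        gp = project_group(control_matrix, space)
        expected = space.control_variance / space.control_variance.sum()
        assert np.allclose(gp.variance_fraction, expected)

    def test_shift_along_loading_moves_one_component(self, control_matrix):
        space = fit_control_space(control_matrix)
        cs = project_group(control_matrix, space)
        k = 2
        shifted_z = space.zscore(control_matrix) + 1.5 * space.components[k]
        shifted = shifted_z * space.sd + space.mean
        gp = project_group(shifted, space, control_scores=cs.scores)
        assert gp.mean_diff[k] == pytest.approx(1.5)
        others = np.delete(gp.mean_diff, k)
        assert np.abs(others).max() < 1e-10

    def test_projection_is_isometry(self, control_matrix, rng):
        space = fit_control_space(control_matrix)
        group = rng.standard_normal((12, 6)) * 2 + 1
        gp = project_group(group, space)
        z = space.zscore(group)
        assert gp.scores.var(axis=0, ddof=1).sum() == pytest.approx(
            z.var(axis=0, ddof=1).sum()
        )

    def test_metric_mismatch_rejected(self, control_matrix, rng):
        space = fit_control_space(control_matrix)
        with pytest.raises(ValueError):
            project_group(
                pd.DataFrame(rng.standard_normal((5, 3)),
                             columns=["a", "b", "c"]),
                space,
            )


class TestHighContributionPcs:
    def test_identical_group_selects_nothing(self, control_matrix):
        space = fit_control_space(control_matrix)
        cs = project_group(control_matrix, space)
        assert high_contribution_pcs(cs, cs.scores) == []

    def test_variance_without_mean_shift_not_selected(self, rng):
        ctrl = rng.standard_normal((40, 4))
        space = fit_control_space(ctrl)
        cs = project_group(ctrl, space)
        grp = rng.standard_normal((20, 4))
        grp[:, :] = space.zscore(grp * 0 + space.mean)  # zeros
        scores = rng.standard_normal((20, 4))
        scores[:, 1] *= 3  # inflate variance on component 1, mean ~ 0
        scores[:, 1] -= scores[:, 1].mean()  # force exact zero mean diff
        from phenotrack.eigenstats import GroupProjection

        var = scores.var(axis=0, ddof=1)
        gp = GroupProjection(scores=scores, variance_fraction=var / var.sum(),
                             mean_diff=scores.mean(axis=0))
        assert 1 not in high_contribution_pcs(gp, cs.scores)

    def test_planted_shift_selected(self):
        rng = np.random.default_rng(0)
        cov = np.full((8, 8), 0.7)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        ctrl = rng.standard_normal((30, 8)) @ chol.T
        space = fit_control_space(ctrl)
        cs = project_group(ctrl, space)
        shift = 3 * np.sqrt(space.control_variance[0]) * space.components[0]
        grp = rng.standard_normal((12, 8)) @ chol.T + shift
        gp = project_group(grp, space, control_scores=cs.scores)
        assert high_contribution_pcs(gp, cs.scores) == [0]

    def test_invariant_to_loading_sign_flip(self, control_matrix, rng):
        space = fit_control_space(control_matrix)
        cs = project_group(control_matrix, space)
        grp = control_matrix[:12] + 2 * space.components[0] * space.sd
        sel_a = high_contribution_pcs(
            project_group(grp, space, control_scores=cs.scores), cs.scores
        )
        space.components[0] *= -1
        cs2 = project_group(control_matrix, space)
        sel_b = high_contribution_pcs(
            project_group(grp, space, control_scores=cs2.scores), cs2.scores
        )
        assert sel_a == sel_b


class TestVarianceRatio:
    def test_equal_samples_give_f_one_p_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        f, p = variance_ratio_test(x, x.copy())
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        # var(1,2,3)=1, var(2,4,6)=4
        f, _ = variance_ratio_test(np.array([1, 2, 3]), np.array([2, 4, 6]))
        assert f == pytest.approx(0.25)

    def test_zero_control_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_test(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestCohensD:
    def test_identical_groups(self, rng):
        x = rng.standard_normal(20)
        assert cohens_d(x, x.copy()) == pytest.approx(0.0)

    def test_degenerate_zero_pooled_sd(self):
        assert np.isnan(cohens_d(np.array([0.0, 0.0]), np.array([1.0, 1.0])))

    def test_unit_separation_limit(self, rng):
        a = rng.standard_normal(4000) + 1.0
        b = rng.standard_normal(4000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.08)


class TestSpearmanPermutation:
    def test_monotone_pair_has_rho_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        rho, _ = spearman_permutation(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_exact_p_matches_brute_force_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        rho, p = spearman_permutation(x, y)
        rho_obs = stats.spearmanr(x, y).statistic
        null = [
            stats.spearmanr(x, np.array(perm)).statistic
            for perm in itertools.permutations(y)
        ]
        p_oracle = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in null])
        assert rho == pytest.approx(rho_obs)
        assert p == pytest.approx(p_oracle)

    def test_monte_carlo_close_to_exact(self, rng):
        x = rng.standard_normal(7)
        y = rng.standard_normal(7) + 0.5 * x
        _, p_exact = spearman_permutation(x, y, exact_max_n=9)
        _, p_mc = spearman_permutation(x, y, exact_max_n=0, n_mc=50_000,
                                       rng=np.random.default_rng(1))
        se = np.sqrt(p_exact * (1 - p_exact) / 50_000)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / 50_000

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_permutation(np.ones(5), np.arange(5.0))


class TestCorrelationNetwork:
    def test_planted_monotone_edge_found(self, rng):
        n = 12
        x = rng.standard_normal(n)
        df = pd.DataFrame({
            "mouse": [f"m{i}" for i in range(n)],
            "group": "control",
            "a": x, "b": np.exp(x),               # rho = 1
            "c": rng.standard_normal(n),
        })
        edges = correlation_network(df, alpha=0.01, seed=0)
        pairs = set(map(tuple, edges[["metric_a", "metric_b"]].to_numpy()))
        assert ("a", "b") in pairs

    def test_pairwise_complete_and_min_n(self, rng):
        df = pd.DataFrame({
            "a": [1.0, 2, 3, np.nan, 5, 6],
            "b": [2.0, 1, 4, 4, np.nan, 6],
            "c": [np.nan] * 4 + [1.0, 2.0],       # only 2 complete pairs
        })
        edges = correlation_network(df, alpha=1.1, keep_all=True, seed=0)
        ab = edges[(edges.metric_a == "a") & (edges.metric_b == "b")]
        assert int(ab["n"].iloc[0]) == 4
        assert not ((edges.metric_a == "c") | (edges.metric_b == "c")).any()

    def test_false_edge_rate_matches_binomial_expectation(self):
        """Independent metrics, 20 mice, 10 metrics: expected false edges
        at alpha=0.01 is 0.45 of the 45 pairs; check the mean over seeds
        against a 3-sigma binomial band."""
        n_seeds, total = 30, 0
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            df = pd.DataFrame(rng.standard_normal((20, 10)),
                              columns=[f"m{i}" for i in range(10)])
            edges = correlation_network(df, alpha=0.01, method="t", seed=s)
            total += len(edges)
        expected = 0.01 * 45 * n_seeds
        sd = np.sqrt(0.01 * 0.99 * 45 * n_seeds)
        assert abs(total - expected) <= 3 * sd + 1


class TestKsCompare:
    def test_identical_samples_d_zero(self, rng):
        x = rng.standard_normal(10)
        d, _ = ks_compare(x, x.copy())
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_d_one(self):
        d, p = ks_compare(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        assert d == pytest.approx(1.0)

    def test_small_n_p_matches_enumeration_oracle(self, rng):
        a = rng.standard_normal(4)
        b = rng.standard_normal(4) + 0.5
        d_obs, p = ks_compare(a, b)
        pooled = np.concatenate([a, b])

        def ks_d(x, y):
            grid = np.sort(pooled)
            fx = np.searchsorted(np.sort(x), grid, "right") / len(x)
            fy = np.searchsorted(np.sort(y), grid, "right") / len(y)
            return np.max(np.abs(fx - fy))

        ds = []
        for idx in itertools.combinations(range(8), 4):
            m = np.zeros(8, dtype=bool)
            m[list(idx)] = True
            ds.append(ks_d(pooled[m], pooled[~m]))
        p_oracle = np.mean(np.array(ds) >= d_obs - 1e-12)
        assert p == pytest.approx(p_oracle)
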