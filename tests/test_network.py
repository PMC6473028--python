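import numpy as np
import pytest

from metabnet.network import (
    PartialCorrelationMatrix,
    binarize_at_sparsity,
    default_sparsity_grid,
    partial_correlation,
    sparsity_sweep,
)

from conftest import make_table


def brute_force_partial_corr(signals, design):
    """Oracle: per-column least squares on [1, design], then residual Pearson."""
    n, r = signals.shape
    X = np.column_stack([np.ones(n), design])
    resid = np.empty_like(signals, dtype=float)
    for j in range(r):
        beta, *_ = np.linalg.lstsq(X, signals[:, j], rcond=None)
        resid[:, j] = signals[:, j] - X @ beta
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            out[i, j] = out[j, i] = np.corrcoef(resid[:, i], resid[:, j])[0, 1]
    return out


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(20, 5))
        table = make_table(sig)
        pc = partial_correlation(table, covariates=[])
        assert np.allclose(pc.values, np.corrcoef(sig.T), atol=1e-12)

    def test_duplicated_roi_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(15, 4))
        sig[:, 3] = sig[:, 0]
        pc = partial_correlation(make_table(sig), covariates=["age"])
        assert pc.values[0, 3] == pytest.approx(1.0, abs=1e-10)

    def test_fixed_fixture_matches_residualization_oracle(self):
        # 6 subjects, 3 ROIs, age covariate: frozen values
        sig = np.array([
            [1.2, 0.7, 2.1],
            [1.5, 0.9, 1.8],
            [0.9, 1.1, 2.4],
            [1.8, 0.6, 1.5],
            [1.1, 1.0, 2.2],
            [1.6, 0.8, 1.7],
        ])
        age = np.array([56.0, 60.0, 63.0, 67.0, 70.0, 74.0])
        table = make_table(sig, age=age)
        pc = partial_correlation(table, covariates=["age"])
        oracle = brute_force_partial_corr(sig, age[:, None])
        assert np.allclose(pc.values, oracle, atol=1e-10)

    def test_matches_inverse_covariance_oracle(self):
        # second oracle: with all other ROIs controlled too, the pairwise
        # partial correlation of residuals equals the normalized negated
        # precision entry; here we verify the pairwise estimator against
        # explicit residualization on a random full-rank design instead
        rng = np.random.default_rng(2)
        sig = rng.normal(size=(30, 6))
        design = np.column_stack([rng.normal(size=30), rng.integers(0, 2, 30)])
        table = make_table(sig, age=design[:, 0], sex=design[:, 1])
        pc = partial_correlation(table, covariates=["age", "sex"])
        assert np.allclose(pc.values, brute_force_partial_corr(sig, design), atol=1e-10)

    def test_two_covariate_full_precision_identity(self):
        # on 3 variables, partialling the third out of a pair equals the
        # normalized inverse-covariance entry (textbook identity)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(500, 3))
        x[:, 1] += 0.6 * x[:, 0]
        x[:, 2] += 0.4 * x[:, 0] - 0.3 * x[:, 1]
        table = make_table(x[:, :2], age=x[:, 2])
        pc = partial_correlation(table, covariates=["age"])
        theta = np.linalg.inv(np.cov(x.T))
        expected = -theta[0, 1] / np.sqrt(theta[0, 0] * theta[1, 1])
        assert pc.values[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_too_few_subjects_rejected(self):
        sig = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ValueError, match="subjects"):
            partial_correlation(make_table(sig), covariates=["age", "sex"])

    def test_rank_deficient_design_rejected(self):
        sig = np.random.default_rng(0).normal(size=(10, 3))
        table = make_table(sig, age=np.full(10, 60.0))  # constant age
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(table, covariates=["age"])

    def test_zero_variance_residual_reported_not_fatal(self):
        sig = np.random.default_rng(0).normal(size=(10, 3))
        sig[:, 2] = 5.0
        pc = partial_correlation(make_table(sig), covariates=[])
        assert pc.undefined_pairs == [(0, 2), (1, 2)]
        assert np.isnan(pc.values[0, 2])

    def test_symmetry_and_diagonal_enforced(self):
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            PartialCorrelationMatrix(bad, roi_names=["a", "b"])


class TestBinarize:
    def test_90_node_matrix_at_28_percent_has_1121_edges(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(90, 90))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        adj = binarize_at_sparsity(v, 0.28)
        assert adj.sum() // 2 == 1121  # round(0.28 * 4005)
        assert np.array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)

    def test_all_ties_resolved_lexicographically(self):
        v = np.full((6, 6), 0.5)
        np.fill_diagonal(v, 1.0)
        adj = binarize_at_sparsity(v, 0.28)  # round(0.28*15) = 4 edges
        iu, ju = np.nonzero(np.triu(adj, 1))
        assert list(zip(iu, ju)) == [(0, 1), (0, 2), (0, 3), (0, 4)]

    def test_matches_full_sort_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(8, 13))
            v = rng.normal(size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            s = rng.uniform(0.1, 0.4)
            adj = binarize_at_sparsity(v, s)
            # oracle: sort every unordered pair by value, take the top k
            pairs = [(v[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
            pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
            k = int(np.round(s * len(pairs)))
            expected = {(i, j) for _, i, j in pairs[:k]}
            got = set(zip(*np.nonzero(np.triu(adj, 1))))
            assert got == expected

    def test_signed_ranking_prefers_positive_over_strong_negative(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.2
        v[0, 2] = v[2, 0] = -0.9
        v[1, 2] = v[2, 1] = 0.1
        adj = binarize_at_sparsity(v, 0.34)  # 1 edge
        assert adj[0, 1] == 1 and adj[0, 2] == 0
        adj_abs = binarize_at_sparsity(v, 0.34, absolute=True)
        assert adj_abs[0, 2] == 1

    def test_zero_edge_sparsity_rejected(self):
        v = np.eye(4)
        with pytest.raises(ValueError, match="zero edges"):
            binarize_at_sparsity(v, 0.01)


class TestSparsitySweep:
    def test_default_grid_has_35_levels(self):
        grid = default_sparsity_grid()
        assert len(grid) == 35
        assert grid[0] == pytest.approx(0.06)
        assert grid[-1] == pytest.approx(0.40)

    def test_stack_is_nested_and_consistent(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(30, 30))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        stack = sparsity_sweep(v)
        assert len(stack) == 35
        prev = None
        for s in stack:
            adj = stack[float(s)]
            assert np.array_equal(adj, binarize_at_sparsity(v, float(s)))
            if prev is not None:
                assert np.all(prev <= adj)  # edges only ever added
            prev = adj

    def test_grid_outside_range_rejected(self):
        v = np.eye(10)
        with pytest.raises(ValueError, match="0.06"):
            sparsity_sweep(v, grid=[0.01, 0.2])
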