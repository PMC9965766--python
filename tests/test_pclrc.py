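import numpy as np
import pytest

from metabonet.pclrc import (
    build_network,
    clr_filter,
    pclrc_infer,
    spearman_matrix,
)
from metabonet.synthetic_data import (
    differential_block_design,
    null_two_group_design,
    simulate,
)


class TestSpearman:
    def test_monotone_relations(self):
        x = np.array([1.0, 4.0, 2.0, 9.0, 6.0])
        m = np.column_stack([x, 2 * x + 7, -(x**3)])
        r = spearman_matrix(m)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        """(1,2,3,4,5) vs (3,1,2,5,4): d = (-2,1,1,-1,1), sum d^2 = 8,
        r = 1 - 6*8/(5*24) = 0.6."""
        m = np.column_stack([[1, 2, 3, 4, 5], [3, 1, 2, 5, 4]])
        r = spearman_matrix(m.astype(float))
        assert r[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_constant_column_is_zero_with_warning(self):
        m = np.column_stack([[1.0, 2, 3, 4], [5.0, 5, 5, 5]])
        with pytest.warns(UserWarning, match="constant"):
            r = spearman_matrix(m)
        assert r[0, 1] == 0.0
        assert r[0, 0] == 1.0

    def test_average_rank_ties_match_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        m = rng.integers(0, 4, size=(30, 5)).astype(float)  # heavy ties
        r = spearman_matrix(m)
        expected = stats.spearmanr(m).statistic
        np.testing.assert_allclose(r, expected, atol=1e-12)


class TestClr:
    def test_uniform_offdiagonal_gives_zero(self):
        m = np.full((5, 5), 0.4)
        np.fill_diagonal(m, 1.0)
        assert np.all(clr_filter(m) == 0.0)

    def test_strong_pair_has_largest_score(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        m[0, 2] = m[2, 0] = 0.1
        m[1, 2] = m[2, 1] = 0.1
        z = clr_filter(m)
        iu = np.triu_indices(3, 1)
        assert z[0, 1] == max(z[iu])
        assert z[0, 1] > z[0, 2] and z[0, 1] > z[1, 2]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, size=(8, 8))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        perm = rng.permutation(8)
        z = clr_filter(m)
        z_perm = clr_filter(m[np.ix_(perm, perm)])
        np.testing.assert_allclose(z_perm, z[np.ix_(perm, perm)], atol=1e-12)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            clr_filter(np.arange(9.0).reshape(3, 3))
        m = -np.ones((3, 3))
        with pytest.raises(ValueError, match="non-negative"):
            clr_filter(m)


class TestPclrc:
    def test_single_iteration_is_binary(self):
        am = simulate(null_two_group_design(n_a=40, n_b=2, n_metabolites=15, seed=0))
        res = pclrc_infer(am.group_values("A"), n_iterations=1, seed=0)
        assert set(np.unique(res.P)) <= {0.0, 1.0}

    def test_full_fraction_equals_fulldata_top_quantile(self):
        am = simulate(null_two_group_design(n_a=40, n_b=2, n_metabolites=15, seed=1))
        x = am.group_values("A")
        res = pclrc_infer(x, n_iterations=7, subsample_fraction=1.0,
                          retention_quantile=0.3, seed=5)
        assert set(np.unique(res.P)) <= {0.0, 1.0}
        # oracle: top 30% of nonzero full-data CLR scores
        c = clr_filter(spearman_matrix(x) ** 2)
        iu = np.triu_indices(15, 1)
        vals = c[iu]
        thr = np.quantile(vals[vals > 0], 0.7)
        np.testing.assert_array_equal(res.P[iu], (vals >= thr).astype(float))

    def test_deterministic_given_seed(self):
        am = simulate(null_two_group_design(n_a=30, n_b=2, n_metabolites=10, seed=2))
        x = am.group_values("A")
        a = pclrc_infer(x, n_iterations=25, seed=9)
        b = pclrc_infer(x, n_iterations=25, seed=9)
        np.testing.assert_array_equal(a.P, b.P)

    def test_rank_invariance_under_monotone_transform(self):
        """P depends on the data only through column ranks: log-transforming
        every metabolite leaves it exactly unchanged at matched seeds."""
        am = simulate(null_two_group_design(n_a=60, n_b=2, seed=3))
        x = am.group_values("A")
        a = pclrc_infer(x, n_iterations=50, seed=4)
        b = pclrc_infer(np.log(x), n_iterations=50, seed=4)
        assert np.mean(np.abs(a.P - b.P)) < 0.02
        np.testing.assert_array_equal(a.P, b.P)

    def test_mc_error_shrinks_with_iterations(self):
        am = simulate(differential_block_design(n_a=60, n_b=20, block_size=5,
                                                n_metabolites=30, seed=5))
        x = am.group_values("CRC")
        p100 = [pclrc_infer(x, n_iterations=100, seed=s).P for s in range(4)]
        p400 = [pclrc_infer(x, n_iterations=400, seed=s + 10).P for s in range(4)]
        sd100 = np.std(p100, axis=0).mean()
        sd400 = np.std(p400, axis=0).mean()
        assert sd400 < sd100  # ~1/sqrt(4) in expectation

    def test_too_few_samples_rejected(self):
        x = np.random.default_rng(0).standard_normal((10, 5))
        with pytest.raises(ValueError, match="at least 20"):
            pclrc_infer(x)


class TestBuildNetwork:
    def _result(self):
        am = simulate(differential_block_design(n_a=60, n_b=20, block_size=5,
                                                n_metabolites=20, seed=7))
        return pclrc_infer(am.group_values("CRC"), n_iterations=100, seed=7)

    def test_zero_thresholds_give_complete_graph_on_positive_p(self):
        res = self._result()
        net = build_network(res, p_min=0.0, r_min=0.0)
        iu = np.triu_indices(20, 1)
        assert net.n_edges == int(np.sum(res.P[iu] > 0))
        assert len(net.nodes) == 20

    def test_impossible_threshold_gives_empty_edge_set(self):
        net = build_network(self._result(), p_min=1.01)
        assert net.n_edges == 0
        assert len(net.nodes) == 20  # isolated nodes kept

    def test_planted_block_edges_recovered_at_defaults(self):
        res = self._result()
        net = build_network(res, p_min=0.95, r_min=0.6)
        block = [res.metabolite_names[i] for i in range(5)]
        within = [
            (u, v) for u, v in net.graph.edges
            if u in block and v in block
        ]
        cross = [
            (u, v) for u, v in net.graph.edges
            if (u in block) != (v in block)
        ]
        assert len(within) >= 6  # most of the 10 block pairs survive
        assert len(cross) == 0
        for _, _, d in net.graph.edges(data=True):
            assert d["probability"] >= 0.95 and abs(d["weight"]) >= 0.6
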