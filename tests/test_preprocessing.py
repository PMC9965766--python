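from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabonet.data_io import AbundanceMatrix
from metabonet.pclrc import spearman_matrix
from metabonet.preprocessing import (
    blom_transform,
    blom_transform_matrix,
    detect_outliers,
    remove_outliers,
    sqrt_transform,
)
from metabonet.synthetic_data import SyntheticDesign, simulate

# independent probit oracle: stdlib normal quantile, not scipy
probit = NormalDist().inv_cdf


class TestBlom:
    def test_middle_of_three_maps_to_zero(self):
        out = blom_transform([10, 20, 30])
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_normal_quantiles(self):
        out = blom_transform([1, 2, 3, 4, 5])
        k = 3.0 / 8.0
        expected = [probit((r - k) / (5 - 2 * k + 1)) for r in range(1, 6)]
        np.testing.assert_allclose(out, expected, atol=1e-9)
        assert out[4] == pytest.approx(1.17986, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.integers(min_value=-10**4, max_value=10**4),
            min_size=3, max_size=40, unique=True,
        )
    )
    def test_monotone_map_leaves_output_unchanged(self, xs):
        """Blom output depends only on ranks: applying an arctan-style
        strictly monotone map to the input leaves it unchanged, and the
        output is a permutation of the n fixed Blom quantiles."""
        x = np.array(xs, dtype=float)
        out = blom_transform(x)
        out2 = blom_transform(np.arctan(x / 1e4) * 3 + 7)
        np.testing.assert_allclose(out, out2, atol=1e-12)
        n = len(xs)
        k = 3.0 / 8.0
        quantiles = sorted(probit((r - k) / (n - 2 * k + 1)) for r in range(1, n + 1))
        np.testing.assert_allclose(sorted(out), quantiles, atol=1e-9)

    def test_ties_get_average_ranks(self):
        out = blom_transform([1.0, 1.0, 5.0])
        assert out[0] == pytest.approx(out[1])
        assert out[0] < out[2]

    def test_all_identical_is_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            blom_transform([2.0, 2.0, 2.0])

    def test_spearman_matrix_invariant_under_transform(self):
        d = SyntheticDesign(n_per_group={"A": 50}, n_metabolites=8, seed=11)
        am = simulate(d)
        before = spearman_matrix(am.group_values("A"))
        after = spearman_matrix(blom_transform_matrix(am).group_values("A"))
        np.testing.assert_allclose(before, after, atol=1e-12)


class TestSqrt:
    def test_elementwise_square_root(self, small_matrix):
        out = sqrt_transform(small_matrix)
        np.testing.assert_allclose(
            out.values.to_numpy() ** 2, small_matrix.values.to_numpy(), rtol=1e-12
        )

    def test_perfect_squares(self):
        values = pd.DataFrame(
            {"m1": [0.0, 1.0, 4.0], "m2": [9.0, 16.0, 25.0]},
            index=pd.Index(["a", "b", "c"], name="sample_id"),
        )
        am = AbundanceMatrix(values=values, groups=pd.Series(["g"] * 3, index=values.index))
        np.testing.assert_array_equal(
            sqrt_transform(am).values.to_numpy(), [[0, 3], [1, 4], [2, 5]]
        )

    def test_negative_rejected(self, small_matrix):
        bad = small_matrix.with_values(-small_matrix.values, scale="int")
        with pytest.raises(ValueError):
            sqrt_transform(bad)


def _gaussian_am(n, p, seed, shift_first_sample=0.0):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, p))
    if shift_first_sample:
        v[0] += shift_first_sample
    values = pd.DataFrame(
        v, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        columns=[f"m{j}" for j in range(p)],
    )
    return AbundanceMatrix(
        values=values, groups=pd.Series(["g"] * n, index=values.index), scale="int"
    )


class TestOutliers:
    def test_extreme_sample_is_flagged(self):
        am = _gaussian_am(100, 30, seed=0, shift_first_sample=10.0)
        report = detect_outliers(am)
        assert "s0" in report.removed_sample_ids

    def test_confidence_one_flags_nothing(self):
        am = _gaussian_am(60, 10, seed=1, shift_first_sample=10.0)
        report = detect_outliers(am, confidence=1.0)
        assert report.removed_sample_ids == []

    def test_invariant_to_sample_and_metabolite_order(self):
        am = _gaussian_am(80, 12, seed=2, shift_first_sample=6.0)
        report = detect_outliers(am)
        rng = np.random.default_rng(3)
        rows = rng.permutation(am.sample_ids)
        cols = rng.permutation(am.metabolite_names)
        shuffled = AbundanceMatrix(
            values=am.values.loc[rows, cols],
            groups=am.groups.loc[rows],
            scale="int",
        )
        report2 = detect_outliers(shuffled)
        assert set(report.removed_sample_ids) == set(report2.removed_sample_ids)

    def test_constant_metabolite_dropped_with_warning(self):
        am = _gaussian_am(50, 5, seed=4)
        vals = am.values.copy()
        vals["m0"] = 3.14
        am2 = am.with_values(vals)
        with pytest.warns(UserWarning, match="constant"):
            detect_outliers(am2)

    def test_remove_outliers_drops_flagged(self):
        am = _gaussian_am(100, 30, seed=5, shift_first_sample=10.0)
        clean, report = remove_outliers(am)
        assert clean.n_samples == 100 - len(report.removed_sample_ids)
        assert "s0" not in clean.sample_ids
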