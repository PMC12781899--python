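"""Benchmark metrics: closed forms, symmetries and cross-checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotmap import metrics as M


TRUTH = np.array([0.1, 0.2, 0.7])
PRED = np.array([0.2, 0.1, 0.7])


class TestPCC:
    def test_identity(self):
        assert M.pcc(TRUTH, TRUTH) == pytest.approx(1.0)

    def test_negated_affine(self):
        assert M.pcc(TRUTH, -TRUTH + 1.0) == pytest.approx(-1.0)

    def test_hand_computed(self):
        t, p = TRUTH, PRED
        cov = np.mean((t - t.mean()) * (p - p.mean()))
        want = cov / (t.std() * p.std())
        assert M.pcc(t, p) == pytest.approx(want)

    def test_constant_column_reported_missing(self):
        assert np.isnan(M.pcc(np.ones(3), TRUTH))


class TestSSIM:
    def test_identity_is_exactly_one(self):
        assert M.ssim(TRUTH, TRUTH) == pytest.approx(1.0)

    def test_symmetry(self):
        assert M.ssim(TRUTH, PRED) == pytest.approx(M.ssim(PRED, TRUTH))

    def test_degenerate_columns_hand_value(self):
        # zero vector vs constant ones: both min-max scale to zeros,
        # so numerator and denominator both reduce to C1^2 * C2^2
        assert M.ssim(np.ones(4), np.zeros(4)) == pytest.approx(1.0)

    def test_hand_value_nondegenerate(self):
        t = M._minmax(TRUTH.copy())
        p = M._minmax(PRED.copy())
        cov = np.mean((t - t.mean()) * (p - p.mean()))
        want = ((2 * p.mean() * t.mean() + 0.01**2) * (2 * cov + 0.03**2)) / (
            (p.mean() ** 2 + t.mean() ** 2 + 0.01**2)
            * (p.std() ** 2 + t.std() ** 2 + 0.03**2)
        )
        assert M.ssim(TRUTH, PRED) == pytest.approx(want)


class TestRMSE:
    def test_identity_zero(self):
        assert M.rmse_z(TRUTH, TRUTH) == 0.0

    def test_affine_invariance(self):
        assert M.rmse_z(TRUTH, 3.2 * TRUTH + 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_opposite_zscores(self):
        # z-scores (1,-1) vs (-1,1): RMSE = 2
        assert M.rmse_z(np.array([0.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(2.0)

    def test_constant_column_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            M.rmse_z(np.ones(3), TRUTH)


class TestJS:
    def test_identity_zero(self):
        assert M.js(TRUTH, TRUTH) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_log2(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert M.js(a, b) == pytest.approx(np.log(2))
        assert M.js(a, b, base=2) == pytest.approx(1.0)

    def test_symmetry(self):
        assert M.js(TRUTH, PRED) == pytest.approx(M.js(PRED, TRUTH))

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            M.js(np.zeros(3), TRUTH)

    def test_matches_scipy_and_bounded(self):
        from scipy.spatial.distance import jensenshannon

        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(0, 1, 6)
            b = rng.uniform(0, 1, 6)
            ours = M.js(a, b)
            ref = jensenshannon(a / a.sum(), b / b.sum()) ** 2
            assert ours == pytest.approx(ref, abs=1e-10)
            assert ours <= np.log(2) + 1e-12


class TestAccu:
    @pytest.mark.parametrize(
        "truth,pred,want",
        [
            (list("AABB"), list("AABB"), 1.0),
            (list("AABB"), list("BBAA"), 0.0),
            (list("AABB"), list("AABA"), 0.75),
        ],
    )
    def test_fraction_matching(self, truth, pred, want):
        assert M.accu(truth, pred) == pytest.approx(want)

    def test_argmax_types_from_proportions(self):
        props = pd.DataFrame({"A": [0.6, 0.2], "B": [0.4, 0.8]}, index=["s0", "s1"])
        assert list(M.argmax_types(props)) == ["A", "B"]


class TestAS:
    def _means(self, rows):
        return pd.DataFrame(rows, columns=["pcc", "ssim", "accu", "rmse", "js"])

    def test_dominating_method_scores_one(self):
        means = self._means(
            [[0.9, 0.9, 0.9, 0.1, 0.1], [0.5, 0.5, 0.5, 0.5, 0.5], [0.1, 0.1, 0.1, 0.9, 0.9]]
        )
        score = M.as_score(means)
        assert score.iloc[0] == pytest.approx(1.0)
        assert score.iloc[2] == pytest.approx(1.0 / 3)

    def test_three_methods_hand_ranked(self):
        means = self._means(
            [[0.9, 0.5, 0.7, 0.2, 0.5], [0.5, 0.9, 0.5, 0.1, 0.7], [0.7, 0.7, 0.9, 0.3, 0.1]]
        )
        # hand ranks (best=3): pcc (3,1,2) ssim (1,3,2) accu (2,1,3)
        # rmse desc (2,3,1) js desc (2,1,3)
        want_raw = np.array([(3 + 1 + 2 + 2 + 2), (1 + 3 + 1 + 3 + 1), (2 + 2 + 3 + 1 + 3)]) / 5
        np.testing.assert_allclose(M.as_score(means, normalize=False), want_raw)
        np.testing.assert_allclose(M.as_score(means), want_raw / 3)

    def test_ties_get_average_ranks(self):
        means = self._means([[0.5, 0.5, 0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5, 0.5]])
        np.testing.assert_allclose(M.as_score(means, normalize=False), [1.5, 1.5])

    def test_invariant_to_monotone_rescaling(self):
        means = self._means(
            [[0.9, 0.5, 0.7, 0.2, 0.5], [0.5, 0.9, 0.5, 0.1, 0.7], [0.7, 0.7, 0.9, 0.3, 0.1]]
        )
        rescaled = means.copy()
        rescaled["pcc"] = means["pcc"] * 100 + 3
        pd.testing.assert_series_equal(M.as_score(means), M.as_score(rescaled))


class TestKDistance:
    def test_query_at_reference_is_zero(self):
        ref = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert M.k_distance([[0.0, 0.0]], ref, k=1)[0] == 0.0

    def test_hand_mean(self):
        ref = np.array([[1.0, 0.0], [2.0, 0.0], [10.0, 0.0]])
        assert M.k_distance([[0.0, 0.0]], ref, k=2)[0] == pytest.approx(1.5)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(20, 2))
        qry = rng.normal(size=(5, 2))
        base = M.k_distance(qry, ref, k=5)
        shifted = M.k_distance(qry + 7.5, ref + 7.5, k=5)
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_k_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="reduced"):
            out = M.k_distance([[0.0, 0.0]], [[1.0, 0.0]], k=10)
        assert out[0] == pytest.approx(1.0)


class TestBenchmarkReport:
    def test_perfect_prediction_closed_forms(self):
        rng = np.random.default_rng(2)
        raw = rng.dirichlet(np.ones(4), size=10)
        truth = pd.DataFrame(raw, columns=list("ABCD"),
                             index=[f"s{i}" for i in range(10)])
        rep = M.benchmark_report(truth, truth.copy())
        assert np.allclose(rep.per_type["pcc"], 1.0)
        assert np.allclose(rep.per_type["ssim"], 1.0)
        assert np.allclose(rep.per_type["rmse"], 0.0)
        assert np.allclose(rep.per_type["js"], 0.0, atol=1e-12)
        assert rep.accu == 1.0 and rep.rmse_raw == 0.0

    def test_spot_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        truth = pd.DataFrame(rng.dirichlet(np.ones(3), 8), columns=list("ABC"),
                             index=[f"s{i}" for i in range(8)])
        pred = pd.DataFrame(rng.dirichlet(np.ones(3), 8), columns=list("ABC"),
                            index=truth.index)
        rep = M.benchmark_report(truth, pred)
        perm = rng.permutation(truth.index)
        rep_p = M.benchmark_report(truth.loc[perm], pred.loc[perm])
        pd.testing.assert_frame_equal(rep.per_type, rep_p.per_type)

    def test_mismatched_spots_rejected(self):
        t = pd.DataFrame({"A": [1.0]}, index=["s0"])
        p = pd.DataFrame({"A": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="spot sets differ"):
            M.benchmark_report(t, p)


class TestSpotLevelCorrelation:
    def test_planted_marker_fixture_high_median(self, small_pair):
        sc, st_data, truth = small_pair
        corr = M.spot_level_correlation(truth.proportions, st_data, sc=sc,
                                        n_markers=20, seed=0)
        assert corr.median() > 0.8

    def test_two_types_required(self, small_pair):
        sc, st_data, truth = small_pair
        with pytest.raises(ValueError, match="two cell types"):
            M.spot_level_correlation(
                truth.proportions[["type0"]], st_data, sc=sc
            )


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_js_bounded_for_random_distributions(seed):
    rng = np.random.default_rng(seed)
    a = rng.dirichlet(np.ones(5))
    b = rng.dirichlet(np.ones(5))
    assert 0.0 <= M.js(a, b) <= np.log(2) + 1e-12
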