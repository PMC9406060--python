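"""Accuracy, permutation nulls, Top-K, advantage and best-encoded stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ventralenc.evaluation import (
    AccuracyVector,
    advantage_analysis,
    best_encoded_proportions,
    pearson_accuracy,
    permutation_threshold,
    topk_average_accuracy,
)


def two_pass_pearson(x, y):
    """Textbook covariance/variance oracle."""
    mx, my = x.mean(), y.mean()
    cov = np.sum((x - mx) * (y - my))
    return cov / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))


class TestPearsonAccuracy:
    def test_hand_example(self):
        acc = pearson_accuracy(
            np.array([[1, 2, 3, 4]]).T.astype(float), np.array([[2, 1, 4, 3]]).T.astype(float)
        )
        assert acc.rho[0] == pytest.approx(0.6)

    def test_perfect_prediction(self, rng):
        x = rng.standard_normal((10, 3))
        acc = pearson_accuracy(x, x)
        np.testing.assert_allclose(acc.rho, 1.0)

    def test_matches_two_pass_oracle_and_scipy(self, rng):
        m = rng.standard_normal((40, 8))
        p = rng.standard_normal((40, 8))
        acc = pearson_accuracy(m, p)
        for v in range(8):
            assert acc.rho[v] == pytest.approx(two_pass_pearson(m[:, v], p[:, v]), abs=1e-12)
            assert acc.rho[v] == pytest.approx(stats.pearsonr(m[:, v], p[:, v])[0], abs=1e-12)

    def test_constant_column_flagged_undefined(self, rng):
        m = rng.standard_normal((10, 2))
        p = rng.standard_normal((10, 2))
        p[:, 1] = 3.14
        acc = pearson_accuracy(m, p)
        assert np.isfinite(acc.rho[0])
        assert np.isnan(acc.rho[1])
        assert not acc.valid[1]

    def test_shape_and_sample_count_errors(self):
        with pytest.raises(ValueError):
            pearson_accuracy(np.zeros((5, 2)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            pearson_accuracy(np.zeros((2, 2)), np.zeros((2, 2)))


class TestPermutationThreshold:
    def test_symmetric_null_median_near_zero(self, rng):
        m = rng.standard_normal((60, 30))
        p = rng.standard_normal((60, 30))
        r = permutation_threshold(m, p, n_perm=1000, alpha=0.5, seed=0)
        assert abs(r["global"]) < 0.05

    def test_standard_setting_recovers_conventional_threshold(self, rng):
        m = rng.standard_normal((120, 100))
        p = rng.standard_normal((120, 100))
        r = permutation_threshold(m, p, n_perm=1000, alpha=0.001, seed=1)
        assert r["order_statistic"] == 2  # 2nd-largest of 1000
        assert r["global"] == pytest.approx(0.27, abs=0.03)

    def test_undefined_voxels_excluded(self, rng):
        m = rng.standard_normal((30, 3))
        p = rng.standard_normal((30, 3))
        p[:, 0] = 0.0
        r = permutation_threshold(m, p, n_perm=50, alpha=0.1, seed=2)
        assert np.isnan(r["per_voxel"][0]) and np.isfinite(r["per_voxel"][1:]).all()

    def test_invalid_arguments(self, rng):
        m = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            permutation_threshold(m, m, n_perm=0)
        with pytest.raises(ValueError):
            permutation_threshold(m, m, alpha=1.5)


class TestTopK:
    def test_hand_mean(self):
        acc = AccuracyVector(np.array([0.9, 0.5, 0.1]))
        assert topk_average_accuracy(acc, 2) == pytest.approx(0.7)

    def test_k_exceeding_voxels_warns_and_averages_all(self):
        acc = AccuracyVector(np.array([0.2, 0.4]))
        with pytest.warns(UserWarning):
            assert topk_average_accuracy(acc, 300) == pytest.approx(0.3)

    def test_undefined_only_raises(self):
        with pytest.raises(ValueError):
            topk_average_accuracy(AccuracyVector(np.array([np.nan])), 1)


class TestAdvantage:
    def test_enumeration_example(self):
        a = AccuracyVector(np.array([0.5, 0.4, 0.3]))
        b = AccuracyVector(np.array([0.4, 0.5, 0.28]))
        res = advantage_analysis(a, b, threshold=0.27, seed=0)
        assert res.n_joint == 3
        assert res.prop_a == pytest.approx(2 / 3)

    def test_identical_vectors_all_ties(self, rng):
        rho = np.clip(rng.uniform(0.3, 0.9, 20), None, 0.99)
        res = advantage_analysis(AccuracyVector(rho), AccuracyVector(rho.copy()), seed=0)
        assert res.n_ties == res.n_joint
        assert np.isnan(res.prop_a)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_complementarity_over_non_tied_voxels(self, seed):
        r = np.random.default_rng(seed)
        a = AccuracyVector(r.uniform(0.3, 0.95, 50))
        b = AccuracyVector(r.uniform(0.3, 0.95, 50))
        ab = advantage_analysis(a, b, n_perm=10, seed=1)
        ba = advantage_analysis(b, a, n_perm=10, seed=1)
        assert ab.prop_a + ba.prop_a == pytest.approx(1.0)

    def test_no_joint_voxels_raises(self):
        a = AccuracyVector(np.array([0.5, 0.5]))
        b = AccuracyVector(np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            advantage_analysis(a, b, seed=0)

    def test_null_cutoff_tracks_binomial_scale(self, rng):
        # cutoff approx 0.5 + z_{1-alpha} / (2 sqrt(N)) for a coin-flip null
        n = 1000
        a = AccuracyVector(rng.uniform(0.3, 0.9, n))
        b = AccuracyVector(rng.uniform(0.3, 0.9, n))
        res = advantage_analysis(a, b, n_perm=4000, alpha=0.05, seed=5)
        assert res.null_cutoff == pytest.approx(0.5 + 1.645 / (2 * np.sqrt(n)), abs=0.01)


class TestBestEncoded:
    def test_enumeration_example(self):
        models = {
            "A": AccuracyVector(np.array([0.5, 0.1])),
            "B": AccuracyVector(np.array([0.3, 0.4])),
        }
        props = best_encoded_proportions(models, threshold=0.27)
        assert props == {"A": 0.5, "B": 0.5}

    def test_single_model_gets_everything(self):
        props = best_encoded_proportions({"only": AccuracyVector(np.array([0.5, 0.6]))})
        assert props["only"] == 1.0

    def test_inclusion_is_at_least_one_valid(self):
        # second voxel valid only under A; it must still be counted
        models = {
            "A": AccuracyVector(np.array([0.3, 0.9])),
            "B": AccuracyVector(np.array([0.8, 0.1])),
        }
        props = best_encoded_proportions(models, threshold=0.27)
        assert props == {"A": 0.5, "B": 0.5}

    def test_sums_to_one_and_label_equivariant(self, rng):
        rho = {l: rng.uniform(-0.2, 0.9, 200) for l in "ABC"}
        models = {l: AccuracyVector(r) for l, r in rho.items()}
        props = best_encoded_proportions(models)
        assert sum(props.values()) == pytest.approx(1.0)
        rev = best_encoded_proportions(dict(reversed(models.items())))
        for l in "ABC":
            assert props[l] == pytest.approx(rev[l])

    def test_nothing_valid_raises(self):
        with pytest.raises(ValueError):
            best_encoded_proportions({"A": AccuracyVector(np.array([0.0]))})
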