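"""Feature selection, logistic fitting and patch classification."""

import numpy as np
import pytest

from frfx.classifier import (
    ClassifierConfig,
    LogisticModel,
    classify_patches,
    estimate_frfx,
    fit_logistic,
    harvest_patches,
    information_gain,
    kmeans_profiles,
    screen_ttest,
    train_functional_classifier,
)
from frfx.phantom import CaseParams, generate_case
from frfx.radiomics import flr_analysis_mask
from frfx.radiomics.base import standardize
from frfx.radiomics.firstorder import FIRST_ORDER_NAMES

from oracles import naive_information_gain


class TestInformationGain:
    def test_perfect_separator_is_one_bit(self):
        x = np.concatenate([np.zeros(100), np.ones(100)])
        y = np.concatenate([np.zeros(100), np.ones(100)])
        assert information_gain(x, y) == pytest.approx(1.0)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000)
        assert information_gain(x, y) < 0.02

    def test_matches_naive_oracle_on_hand_example(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        y = [0, 0, 1, 0, 1, 1, 0, 1]
        ours = information_gain(np.array(x), np.array(y), n_bins=4)
        ref = naive_information_gain(x, y, n_bins=4)
        assert ours == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        y = (x + rng.normal(size=60)) > 0
        ours = information_gain(x, y.astype(int))
        ref = naive_information_gain(list(x), list(y.astype(int)))
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = (x > 0.3).astype(int)
        a = information_gain(x, y)
        b = information_gain(np.exp(x), y)
        assert a == pytest.approx(b, rel=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            x = rng.normal(size=100)
            y = rng.integers(0, 2, 100)
            ig = information_gain(x, y)
            hy = -(np.mean(y) * np.log2(max(np.mean(y), 1e-12))
                   + (1 - np.mean(y)) * np.log2(max(1 - np.mean(y), 1e-12)))
            assert 0.0 <= ig <= hy + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            information_gain(np.arange(10.0), np.zeros(10))


class TestTtest:
    def test_hand_example(self):
        t, p = screen_ttest(
            np.array([[1.0], [2.0], [3.0], [4.0], [3.0], [4.0], [5.0], [6.0]]),
            np.array([0, 0, 0, 0, 1, 1, 1, 1]),
        )
        assert t[0] == pytest.approx(-2.1909, abs=1e-4)
        from scipy import stats

        ref = stats.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6], equal_var=True)
        assert t[0] == pytest.approx(ref.statistic, rel=1e-9)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_groups(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        t, p = screen_ttest(X, np.array([0, 0, 0, 1, 1, 1]))
        assert t[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_antisymmetric_in_group_swap(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 6 + [1] * 6)
        t1, _ = screen_ttest(X, y)
        t2, _ = screen_ttest(X, 1 - y)
        assert np.allclose(t1, -t2)


class TestKmeans:
    def test_k1_recovers_column_means(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        labels, centroids, inertia = kmeans_profiles(X, k=1, seed=0)
        assert np.allclose(centroids[0], X.mean(axis=0), atol=1e-9)
        assert inertia == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-9)

    def test_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(10, 1, (25, 3))])
        labels, _, _ = kmeans_profiles(X, k=2, seed=0)
        truth = np.array([0] * 25 + [1] * 25)
        agree = max((labels == truth).mean(), (labels == 1 - truth).mean())
        assert agree == 1.0

    def test_inertia_nests(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        _, _, i1 = kmeans_profiles(X, k=1, seed=0)
        _, _, i2 = kmeans_profiles(X, k=2, seed=0)
        assert i2 <= i1

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_profiles(np.zeros((3, 2)), k=4, seed=0)


class TestLogistic:
    def test_separable_data_perfect_training_accuracy(self):
        X = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        coef, intercept = fit_logistic(X, y, l2_strength=0.1)
        p = 1 / (1 + np.exp(-(X.ravel() * coef[0] + intercept)))
        assert np.all((p >= 0.5) == (y == 1))

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5000, 2))
        true = np.array([1.0, -2.0])
        p = 1 / (1 + np.exp(-(X @ true)))
        y = rng.uniform(size=5000) < p
        coef, intercept = fit_logistic(X, y.astype(int), l2_strength=1e-3)
        assert np.allclose(coef, true, atol=0.15)
        assert abs(intercept) < 0.15

    def test_probabilities_strictly_inside_unit_interval(self):
        model = LogisticModel(
            feature_names=["a"],
            coefficients=np.array([50.0]),
            intercept=0.0,
            standardization=None,
        )
        p = model.predict_proba(np.array([[-100.0], [0.0], [100.0]]))
        assert np.all((p > 0) & (p < 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((10, 1)), np.zeros(10))


class TestTrainingChain:
    def test_selection_prefers_location_or_scale_features(self, selection_report):
        """The default textures differ in mean (105 vs 70) and sd (12 vs 20),
        so an intensity location or scale feature must rank top-k."""
        location_scale = {
            "firstorder_Mean",
            "firstorder_Median",
            "firstorder_RootMeanSquared",
            "firstorder_Energy",
            "firstorder_TotalEnergy",
            "firstorder_Variance",
            "firstorder_StandardDeviation",
            "firstorder_10Percentile",
            "firstorder_90Percentile",
        }
        assert set(selection_report.chosen) & location_scale
        assert set(selection_report.chosen) <= set(FIRST_ORDER_NAMES)
        assert len(selection_report.chosen) == 5

    def test_information_gain_ranking_sorted(self, selection_report):
        ig = {n: g for n, g in zip(selection_report.feature_names,
                                   selection_report.information_gain_bits)}
        ranked_ig = [ig[n] for n in selection_report.ranked]
        assert all(a >= b - 1e-12 for a, b in zip(ranked_ig, ranked_ig[1:]))
        assert all(g >= 0 for g in ranked_ig)

    def test_training_patch_accuracy(self, train_cohort, default_model):
        """At default texture contrast the patch classifier separates
        functional from oedema patches almost perfectly."""
        cfg = ClassifierConfig()
        X, y = harvest_patches(train_cohort, cfg)
        Z, params = standardize(X, list(FIRST_ORDER_NAMES))
        cols = [params.names.index(n) for n in default_model.feature_names]
        p = default_model.predict_proba(Z[:, cols])
        accuracy = ((p >= 0.5) == (y == 1)).mean()
        assert accuracy >= 0.9

    def test_kmeans_agreement_reported(self, selection_report):
        assert 0.0 <= selection_report.kmeans_truth_agreement <= 1.0

    def test_model_json_roundtrip(self, default_model):
        clone = LogisticModel.from_json(default_model.to_json())
        assert clone.feature_names == default_model.feature_names
        assert np.allclose(clone.coefficients, default_model.coefficients)
        assert np.allclose(clone.standardization.mean,
                           default_model.standardization.mean)


class TestClassifyVolumes:
    def test_fully_functional_phantom(self, default_model):
        case = generate_case(CaseParams(theta=0.0), seed=87)
        img, seg = case.post
        am = flr_analysis_mask(seg)
        fmap = classify_patches(img, am, default_model)
        frl_cc = am.voxel_count * seg.voxel_volume_cc
        assert abs(fmap.frfx_cc - frl_cc) / frl_cc < 0.1
        probs = fmap.probability[np.isfinite(fmap.probability)]
        assert np.all((probs >= 0) & (probs <= 1))
        assert fmap.frfx_cc <= fmap.analysable_cc + 1e-9

    def test_half_oedema_phantom(self, default_model):
        case = generate_case(CaseParams(theta=0.5), seed=88)
        _, frfx_post = estimate_frfx(case, default_model)
        ratio = frfx_post / case.truth_frl_cc
        assert 0.4 <= ratio <= 0.6

    def test_estimate_monotone_in_theta(self, default_model):
        ratios = []
        for theta in (0.0, 0.25, 0.5, 0.75):
            case = generate_case(CaseParams(theta=theta), seed=55)
            _, frfx_post = estimate_frfx(case, default_model)
            ratios.append(frfx_post / case.truth_frl_cc)
        assert all(a >= b - 0.05 for a, b in zip(ratios, ratios[1:]))

    def test_deterministic(self, default_model, sample_case):
        a = estimate_frfx(sample_case, default_model)
        b = estimate_frfx(sample_case, default_model)
        assert a == b

    def test_pre_study_reads_fully_functional(self, default_model, sample_case):
        frfx_pre, _ = estimate_frfx(sample_case, default_model)
        seg = sample_case.pre[1]
        frl_pre = flr_analysis_mask(seg).voxel_count * seg.voxel_volume_cc
        assert abs(frfx_pre - frl_pre) / frl_pre < 0.1
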