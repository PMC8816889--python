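"""Statistical harness: AUC/F1 oracles, DeLong, regression, windows."""

import numpy as np
import pytest
from scipy import stats

from lofisim.evaluate import (
    choose_patient_threshold,
    delong_test,
    f1_score,
    moving_mean,
    null_model_f1,
    patient_classify,
    roc_auc,
    sensitivity_ratio_curve,
    sensitivity_regression,
    youden_threshold,
)


def mann_whitney_auc(labels, scores):
    """Exhaustive pairwise enumeration oracle for the AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def delong_oracle(labels, sa, sb):
    """From-scratch structural-components DeLong computation (explicit
    loops; independent of the library's rank-based path)."""
    labels = np.asarray(labels)
    pos_idx = np.where(labels == 1)[0]
    neg_idx = np.where(labels == 0)[0]
    m, n = len(pos_idx), len(neg_idx)

    def psi(x, y):
        return 1.0 if y < x else (0.5 if y == x else 0.0)

    out = []
    for s in (sa, sb):
        v10 = np.array([np.mean([psi(s[i], s[j]) for j in neg_idx]) for i in pos_idx])
        v01 = np.array([np.mean([psi(s[i], s[j]) for i in pos_idx]) for j in neg_idx])
        out.append((v10.mean(), v10, v01))
    (auc_a, v10_a, v01_a), (auc_b, v10_b, v01_b) = out
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    z = (auc_a - auc_b) / np.sqrt(var)
    return auc_a, auc_b, z


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_hand_enumerated_example(self):
        auc, _ = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1])
        assert auc == pytest.approx(0.75)  # 3 wins, 1 loss of 4 pairs

    def test_all_tied_scores_give_half(self):
        auc, _ = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(20), 2)  # coarse grid forces ties
        auc, _ = roc_auc(labels, scores)
        assert auc == pytest.approx(mann_whitney_auc(labels, scores), abs=1e-12)


class TestF1:
    def test_perfect(self):
        assert f1_score([0, 1, 1], [0, 1, 1]) == 1.0

    def test_hand_computed(self):
        labels = [1, 1, 1, 1, 0, 0]
        preds = [1, 1, 1, 0, 1, 0]  # TP=3 FP=1 FN=1
        assert f1_score(labels, preds) == pytest.approx(0.75)

    def test_all_negative_predictions(self):
        assert f1_score([0, 1, 0, 1], [0, 0, 0, 0]) == 0.0


class TestNullModel:
    @pytest.mark.parametrize("prevalence", [0.3, 0.5])
    def test_mean_matches_closed_form(self, prevalence):
        n = 400
        labels = np.zeros(n, dtype=int)
        labels[: int(prevalence * n)] = 1
        mean, sd = null_model_f1(labels, trials=500, seed=1)
        expected = 2 * (prevalence * 0.5) / (prevalence + 0.5)
        assert abs(mean - expected) < 3 * sd / np.sqrt(500) + 0.01

    def test_sd_shrinks_with_slice_count(self):
        rng = np.random.default_rng(0)
        small = rng.integers(0, 2, 100)
        large = np.tile(small, 4)
        _, sd_small = null_model_f1(small, trials=400, seed=2)
        _, sd_large = null_model_f1(large, trials=400, seed=2)
        assert sd_large < sd_small


class TestDeLong:
    def test_identical_scores(self):
        labels = [0, 1, 0, 1, 1]
        s = [0.1, 0.9, 0.3, 0.6, 0.8]
        auc_a, auc_b, z, p = delong_test(labels, s, s)
        assert (z, p) == (0.0, 1.0)
        assert auc_a == auc_b

    def test_matches_structural_components_oracle(self):
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1])
        sa = np.array([0.9, 0.8, 0.7, 0.5, 0.4, 0.3, 0.35, 0.2, 0.6, 0.55])
        sb = np.array([0.7, 0.9, 0.4, 0.6, 0.5, 0.2, 0.3, 0.4, 0.3, 0.8])
        auc_a, auc_b, z, p = delong_test(labels, sa, sb)
        o_auc_a, o_auc_b, o_z = delong_oracle(labels, sa, sb)
        assert auc_a == pytest.approx(o_auc_a, abs=1e-12)
        assert auc_b == pytest.approx(o_auc_b, abs=1e-12)
        assert z == pytest.approx(o_z, abs=1e-8)
        assert p == pytest.approx(2 * stats.norm.sf(abs(o_z)), abs=1e-8)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0, 1], [0.1, 0.9], [0.1])

    def test_type_one_error_calibration_quick(self):
        # light version of the null calibration (full run in acceptance)
        rng = np.random.default_rng(3)
        rejections = 0
        trials = 300
        for _ in range(trials):
            latent = rng.normal(size=80)
            labels = (latent + rng.normal(size=80) > 0).astype(int)
            if labels.sum() in (0, 80):
                continue
            sa = latent + rng.normal(scale=1.0, size=80)
            sb = latent + rng.normal(scale=1.0, size=80)
            *_, p = delong_test(labels, sa, sb)
            rejections += p < 0.05
        assert 0.01 < rejections / trials < 0.10


class TestSensitivityRegression:
    def test_generative_recovery_of_size_effect(self):
        rng = np.random.default_rng(0)
        n = 500
        area = rng.uniform(0, 4, n)
        contrast = rng.normal(2.0, 0.5, n)
        p_detect = 1 / (1 + np.exp(-(-1 + 2 * area)))
        detected = (rng.random(n) < p_detect).astype(int)
        res = sensitivity_regression(detected, area, contrast)
        assert res.coef_size > 0
        assert res.p_size < 0.01
        assert res.p_intensity > 0.05

    def test_constant_covariates_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_regression([0, 1] * 10, np.ones(20), np.ones(20))

    def test_too_few_positive_slices_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_regression([1, 0, 1], [1.0, 2.0, 3.0], [0.1, 0.2, 0.3])

    def test_perfect_separation_is_flagged_not_fatal(self):
        area = np.linspace(0, 4, 40)
        detected = (area > 2).astype(int)
        contrast = np.linspace(1, 2, 40)
        res = sensitivity_regression(detected, area, contrast)
        assert res.separation_flag
        assert np.isfinite(res.coef_size)


class TestSensitivityRatio:
    def test_identical_arms_give_unit_ratio(self):
        det = np.array([1, 0, 1, 1, 0, 1, 1, 1])
        area = np.array([0.5, 0.8, 1.5, 2.5, 3.0, 4.5, 6.0, 9.0])
        curve = sensitivity_ratio_curve(det, area, det, area, [1.0, 4.0, 10.0], min_slices=2)
        assert np.allclose(curve.ratio.dropna(), 1.0)

    def test_lf_blind_below_threshold(self):
        area = np.array([0.4, 0.6, 0.8, 2.0, 3.0, 4.0])
        hf = np.array([1, 0, 1, 1, 1, 1])
        lf = np.array([0, 0, 0, 1, 1, 1])
        curve = sensitivity_ratio_curve(hf, area, lf, area, [1.0, 10.0], min_slices=2)
        assert curve.ratio.iloc[0] == 0.0

    def test_largest_threshold_equals_overall_ratio(self):
        rng = np.random.default_rng(1)
        area = rng.uniform(0.5, 10, 40)
        hf = rng.integers(0, 2, 40)
        hf[0] = 1
        lf = rng.integers(0, 2, 40)
        curve = sensitivity_ratio_curve(hf, area, lf, area, [99.0])
        assert curve.ratio.iloc[0] == pytest.approx(lf.mean() / hf.mean())

    def test_zero_hf_sensitivity_flagged_undefined(self):
        curve = sensitivity_ratio_curve([0, 0], [1.0, 2.0], [1, 1], [1.0, 2.0], [5.0])
        assert np.isnan(curve.ratio.iloc[0])
        assert curve.unstable.iloc[0]


class TestPatientLevel:
    def test_window_is_three_slices_at_5mm_thickness(self):
        scores = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        trace, _ = patient_classify(scores, 5.0, threshold=0.5, window_mm=15.0)
        # w = 3: center sees the spike fully diluted to 1/3
        assert trace[2] == pytest.approx(1 / 3)

    def test_all_ones_decides_positive(self):
        _, decision = patient_classify(np.ones(6), 5.0, threshold=1.0)
        assert decision

    def test_moving_mean_matches_brute_force(self):
        rng = np.random.default_rng(2)
        scores = rng.random(10)
        w = 3
        out = moving_mean(scores, w)
        for i in range(10):
            lo, hi = max(0, i - 1), min(10, i + 2)
            assert out[i] == pytest.approx(scores[lo:hi].mean(), abs=1e-15)

    def test_choose_threshold_separable(self):
        thr, flag = choose_patient_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert thr == 0.8
        assert not flag

    def test_choose_threshold_degenerate_flagged(self):
        thr, flag = choose_patient_threshold([0.5, 0.5], [1, 0])
        assert flag

    def test_threshold_is_accuracy_argmax(self):
        rng = np.random.default_rng(5)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        labels[0], labels[1] = 0, 1
        thr, _ = choose_patient_threshold(scores, labels)
        acc = lambda t: ((scores >= t).astype(int) == labels).mean()
        assert all(acc(thr) >= acc(t) for t in scores)


def test_youden_threshold_maximizes_j():
    labels = np.array([0, 0, 1, 1, 1, 0])
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.9, 0.2])
    thr = youden_threshold(labels, scores)
    j = lambda t: ((scores >= t) & (labels == 1)).sum() / 3 - ((scores >= t) & (labels == 0)).sum() / 3
    assert all(j(thr) >= j(t) - 1e-12 for t in scores)
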