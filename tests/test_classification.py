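"""AUC/DeLong/Brier/logistic machinery and the LOOCV density classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retdens import (
    ClassifierConfig,
    auc_mann_whitney,
    bonferroni_level,
    brier,
    delong_auc_ci,
    estimate_pdf,
    fit_logistic,
    loocv_evaluate,
    pooled_domain_transform,
    predict_prob,
    sens_spec,
    summary_feature_baseline,
)
from retdens.synthetic_data import GroupParams, generate_pixel_sample


def exhaustive_auc(scores, y):
    """Independent oracle: average over all (positive, negative) pairs."""
    pos = [s for s, yi in zip(scores, y) if yi == 1]
    neg = [s for s, yi in zip(scores, y) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def small_cohort_densities(tail_a, tail_b, n_per_group, seed, grid=128, npx=600):
    params_a = GroupParams(tail_mass_above_50=tail_a)
    params_b = GroupParams(tail_mass_above_50=tail_b)
    rng = np.random.default_rng(seed)
    samples = []
    y = []
    for i in range(n_per_group):
        samples.append(generate_pixel_sample(params_a, npx, int(rng.integers(2**31))))
        y.append(0)
    for i in range(n_per_group):
        samples.append(generate_pixel_sample(params_b, npx, int(rng.integers(2**31))))
        y.append(1)
    t = pooled_domain_transform(samples)
    return [estimate_pdf(s, t, grid) for s in samples], np.array(y)


class TestAUC:
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=12).filter(
            lambda y: 0 < sum(v > 2 for v in y) < len(y)
        ),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_pair_count(self, raw, seed):
        y = np.array([1 if v > 2 else 0 for v in raw])
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, size=len(y)).astype(float)  # ties likely
        assert auc_mann_whitney(scores, y) == pytest.approx(
            exhaustive_auc(scores, y), abs=1e-12
        )

    def test_perfectly_ranked_hand_case(self):
        p = np.array([0.9, 0.8, 0.3, 0.2])
        y = np.array([1, 1, 0, 0])
        auc, lo, hi = delong_auc_ci(p, y, 0.95)
        assert auc == 1.0 and (lo, hi) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDeLong:
    def test_coverage_matches_nominal_level(self):
        # binormal model with known true AUC = Phi(mu / sqrt(2))
        from scipy.stats import norm

        mu = 1.0
        true_auc = float(norm.cdf(mu / np.sqrt(2)))
        rng = np.random.default_rng(13)
        level = 0.95
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            neg = rng.normal(0, 1, 200)
            pos = rng.normal(mu, 1, 200)
            scores = np.concatenate([neg, pos])
            y = np.concatenate([np.zeros(200, int), np.ones(200, int)])
            _, lo, hi = delong_auc_ci(scores, y, level)
            hits += lo <= true_auc <= hi
        assert abs(hits / n_rep - level) < 0.03

    def test_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(5)
        neg = rng.normal(0, 1, 60)
        pos = rng.normal(0.8, 1, 50)
        scores = np.concatenate([neg, pos])
        y = np.concatenate([np.zeros(60, int), np.ones(50, int)])
        auc, lo, hi = delong_auc_ci(scores, y, 0.95)
        from scipy.stats import norm

        se = (hi - lo) / (2 * norm.ppf(0.975))
        boot = []
        for _ in range(10_000):
            bi = rng.choice(60, 60)
            bj = rng.choice(50, 50)
            boot.append(auc_mann_whitney(np.concatenate([neg[bi], pos[bj]]),
                                         y))
        assert se == pytest.approx(np.std(boot, ddof=1), rel=0.15)

    def test_all_tied_scores_collapse_to_point_ci(self):
        p = np.full(10, 0.5)
        y = np.array([0, 1] * 5)
        auc, lo, hi = delong_auc_ci(p, y, 0.95)
        assert auc == 0.5 and lo == hi == 0.5


class TestBonferroni:
    def test_study_level_three_comparisons(self):
        # overall 95% over three pairwise comparisons -> 98.3% per CI
        assert bonferroni_level(0.05, 3) == pytest.approx(0.983333333, abs=1e-9)
        assert round(100 * bonferroni_level(0.05, 3), 1) == 98.3

    @pytest.mark.parametrize("alpha,k,expected", [(0.05, 1, 0.95), (0.10, 2, 0.95)])
    def test_hand_values(self, alpha, k, expected):
        assert bonferroni_level(alpha, k) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_level(0.0, 3)
        with pytest.raises(ValueError):
            bonferroni_level(0.05, 0)


class TestBrierSensSpec:
    def test_brier_hand_values(self):
        assert brier(np.array([1.0, 0.0]), np.array([1, 0])) == 0.0
        assert brier(np.full(7, 0.5), np.array([0, 1, 0, 1, 1, 0, 0])) == 0.25
        assert brier(np.array([0.8, 0.3]), np.array([1, 0])) == pytest.approx(0.065)

    def test_sens_spec_hand_values(self):
        assert sens_spec(np.array([0.9, 0.1]), np.array([1, 0]), 0.5) == (1.0, 1.0)
        se, sp = sens_spec(np.array([0.9, 0.1]), np.array([1, 0]), 0.0)
        assert (se, sp) == (1.0, 0.0)
        se, sp = sens_spec(
            np.array([0.6, 0.4, 0.6, 0.4]), np.array([1, 1, 0, 0]), 0.5
        )
        assert (se, sp) == (0.5, 0.5)


class TestLogistic:
    def test_symmetric_toy_has_zero_intercept(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        model = fit_logistic(X, y)
        assert abs(model.beta[0]) < 1e-3

    def test_null_labels_give_vanishing_slopes(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 2))
        y = rng.integers(0, 2, 2000)
        model = fit_logistic(X, y)
        assert np.all(np.abs(model.beta[1:]) < 0.1)

    def test_prediction_formula(self):
        model = fit_logistic(np.array([[-1.0], [1.0]]), np.array([0, 1]))
        # x'beta = 0 must give probability 1/2 regardless of coefficients
        x0 = -model.beta[0] / model.beta[1]
        assert predict_prob(model, np.array([[x0]]))[0] == pytest.approx(0.5, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((3, 1)), np.array([1, 1, 1]))


class TestSummaryFeatures:
    def test_five_numbers_hand_case(self):
        feats = summary_feature_baseline([np.array([10.0, 20.0, 30.0, 40.0])])
        np.testing.assert_allclose(feats[0], [25.0, 10.0, 40.0, 17.5, 32.5])

    def test_constant_sample(self):
        feats = summary_feature_baseline([np.full(5, 7.0)])
        np.testing.assert_allclose(feats[0], np.full(5, 7.0))

    def test_not_affine_invariant(self):
        a = np.array([10.0, 20.0, 30.0])
        assert not np.allclose(
            summary_feature_baseline([a]), summary_feature_baseline([2 * a + 5])
        )

    def test_empty_sample_names_subject(self):
        from retdens import PixelSample

        with pytest.raises(ValueError, match="S7"):
            summary_feature_baseline([PixelSample(np.array([]), subject_id="S7")])


class TestLOOCV:
    def test_separated_groups_reach_high_auc(self):
        densities, y = small_cohort_densities(0.05, 0.60, 20, seed=1)
        rep = loocv_evaluate(densities, y)
        assert rep.auc > 0.9
        assert rep.feature_set == "density-based"

    def test_label_permutation_gives_null_auc(self):
        densities, y = small_cohort_densities(0.05, 0.60, 20, seed=2)
        rng = np.random.default_rng(3)
        y_perm = y[rng.permutation(len(y))]
        rep = loocv_evaluate(densities, y_perm)
        assert 0.3 <= rep.auc <= 0.7

    def test_determinism(self):
        densities, y = small_cohort_densities(0.1, 0.4, 5, seed=4, npx=300)
        r1 = loocv_evaluate(densities, y)
        r2 = loocv_evaluate(densities, y)
        np.testing.assert_array_equal(r1.p_hat, r2.p_hat)
        assert r1.auc == r2.auc

    def test_no_leakage_of_held_out_label(self):
        # flipping subject i's label must not change subject i's prediction
        densities, y = small_cohort_densities(0.1, 0.5, 5, seed=5, npx=300)
        rep = loocv_evaluate(densities, y)
        i = 0
        y_flipped = y.copy()
        y_flipped[i] = 1 - y_flipped[i]
        rep_flipped = loocv_evaluate(densities, y_flipped)
        assert rep.p_hat[i] == pytest.approx(rep_flipped.p_hat[i], abs=1e-12)

    def test_affine_rescaled_cohort_identical_density_auc(self):
        # density features see only the pooled-normalised samples
        params_a = GroupParams(tail_mass_above_50=0.1)
        params_b = GroupParams(tail_mass_above_50=0.45)
        rng = np.random.default_rng(6)
        samples = [
            generate_pixel_sample(p, 400, int(rng.integers(2**31)))
            for p in [params_a] * 5 + [params_b] * 5
        ]
        y = np.array([0] * 5 + [1] * 5)
        scaled = [2.0 * s + 5.0 for s in samples]
        reps = []
        for cohort in (samples, scaled):
            t = pooled_domain_transform(cohort)
            dens = [estimate_pdf(s, t, 128) for s in cohort]
            reps.append(loocv_evaluate(dens, y))
        # the unit-interval samples agree up to float rounding of the affine
        # arithmetic, so ranks (hence AUC) are preserved exactly and the
        # probabilities to rounding-amplified tolerance
        assert reps[0].auc == reps[1].auc
        np.testing.assert_allclose(reps[0].p_hat, reps[1].p_hat, atol=1e-3)

    def test_five_number_features_share_the_same_path(self):
        params_a = GroupParams(tail_mass_above_50=0.05)
        params_b = GroupParams(tail_mass_above_50=0.60)
        rng = np.random.default_rng(7)
        samples = [
            generate_pixel_sample(p, 600, int(rng.integers(2**31)))
            for p in [params_a] * 10 + [params_b] * 10
        ]
        y = np.array([0] * 10 + [1] * 10)
        rep = loocv_evaluate(None, y, features=summary_feature_baseline(samples))
        assert rep.feature_set == "five-number-summary"
        assert rep.auc > 0.8

    def test_global_pca_scope_runs(self):
        densities, y = small_cohort_densities(0.1, 0.5, 5, seed=8, npx=300)
        rep = loocv_evaluate(densities, y, ClassifierConfig(pca_scope="global"))
        assert 0.0 <= rep.auc <= 1.0

    def test_ci_level_is_bonferroni_corrected(self):
        densities, y = small_cohort_densities(0.1, 0.5, 5, seed=9, npx=300)
        rep = loocv_evaluate(densities, y)
        assert rep.ci_level == pytest.approx(1 - 0.05 / 3)
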