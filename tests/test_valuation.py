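"""Probability-weighting model: weights, likelihoods, fits, bias indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit

from affectrecall import valuation as vl
from affectrecall.design import build_canonical_design, generate_preference_trials
from affectrecall.valuation import (
    FitResult,
    ValuationError,
    WeightingParams,
    auc_weighting_curve,
    choice_probability,
    compare_models,
    fit_benchmarks,
    fit_preference_model,
    model_free_bias,
    negative_log_likelihood,
    parameter_recovery,
    positive_bias_index,
    weight_probability,
    wof_logistic_contrast,
    wof_logistic_contrast_subject,
)


def _trials(rows):
    """Trial table from (p_left, cond_left, p_right, cond_right, choice)."""
    return pd.DataFrame(rows, columns=["left_prob", "left_condition",
                                       "right_prob", "right_condition",
                                       "choice"])


def _valence_params(dw=1.0, gw=1.0, dl=1.0, gl=1.0, beta=5.0):
    return WeightingParams(arms={"win": (dw, gw), "loss": (dl, gl)},
                           beta=beta, variant="study2_valence")


class TestWeightProbability:
    def test_identity_parameterization(self):
        for p in np.linspace(0.01, 0.99, 25):
            assert weight_probability(p, 1.0, 1.0) == pytest.approx(p, abs=1e-9)

    def test_endpoints(self):
        for d, g in [(0.3, 0.5), (1.0, 1.0), (2.5, 1.8), (5.0, 0.2)]:
            assert weight_probability(0.0, d, g) == 0.0
            assert weight_probability(1.0, d, g) == 1.0

    def test_bounded(self):
        p = np.linspace(0, 1, 101)
        w = weight_probability(p, 3.0, 0.4)
        assert np.all((w >= 0) & (w <= 1))

    @settings(max_examples=100, derandomize=True)
    @given(delta=st.floats(0.05, 10.0), gamma=st.floats(0.05, 10.0))
    def test_monotone_nondecreasing(self, delta, gamma):
        grid = np.linspace(0.005, 0.995, 99)
        w = weight_probability(grid, delta, gamma)
        assert np.all(np.diff(w) >= -1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValuationError):
            weight_probability(0.5, 0.0, 1.0)
        with pytest.raises(ValuationError):
            weight_probability(0.5, 1.0, -1.0)


class TestChoiceProbability:
    def test_equal_weighted_values(self):
        t = _trials([(0.6, "post_win", 0.6, "post_win", "left")])
        p = choice_probability(t, _valence_params(beta=8.0))
        assert p[0] == pytest.approx(0.5)

    def test_beta_zero_is_random(self):
        t = _trials([(0.9, "post_win", 0.1, "post_loss", "left")])
        params = WeightingParams(arms={"win": (0.5, 1.5), "loss": (2.0, 0.5)},
                                 beta=0.0, variant="study2_valence")
        assert choice_probability(t, params)[0] == pytest.approx(0.5)

    def test_known_sigmoid_value(self):
        # identity weighting, w difference 0.2, beta 5 -> logistic(1.0)
        t = _trials([(0.7, "baseline_pre", 0.5, "baseline_pre", "left")])
        p = choice_probability(t, _valence_params(beta=5.0))
        assert p[0] == pytest.approx(expit(1.0), abs=1e-6)
        assert p[0] == pytest.approx(0.7311, abs=1e-4)

    def test_sided_variant_uses_side_arms(self):
        t = _trials([(0.7, "baseline_pre", 0.7, "baseline_pre", "left")])
        params = WeightingParams(arms={"left": (0.5, 1.0), "right": (2.0, 1.0)},
                                 beta=3.0, variant="study1_sided")
        # same objective p but the left arm elevates: P(left) > 0.5
        assert choice_probability(t, params)[0] > 0.6

    def test_unresolvable_condition(self):
        t = _trials([(0.7, "post_win", 0.5, "post_loss", "left")])
        params = WeightingParams(arms={"left": (1, 1)}, beta=1.0,
                                 variant="study1_sided")
        # sided variant ignores conditions; a valence fit missing an arm fails
        bad = WeightingParams(arms={"win": (1, 1)}, beta=1.0, variant="bogus")
        with pytest.raises(ValuationError):
            choice_probability(t, bad)


class TestNegativeLogLikelihood:
    def test_matches_naive_recomputation(self, rng):
        design = build_canonical_design("study2")
        trials = generate_preference_trials(design, seed=2).head(20)
        trials = trials.assign(
            choice=rng.choice(["left", "right"], len(trials)))
        params = _valence_params(0.8, 1.4, 1.2, 0.7, beta=4.0)
        # oracle: per-trial recomputation with scalar arithmetic
        expected = 0.0
        for row in trials.itertuples():
            def w(p, cond):
                if cond == "post_win":
                    return weight_probability(p, 0.8, 1.4)
                if cond == "post_loss":
                    return weight_probability(p, 1.2, 0.7)
                return np.clip(p, 1e-6, 1 - 1e-6)
            pl = expit(4.0 * (w(row.left_prob, row.left_condition)
                              - w(row.right_prob, row.right_condition)))
            expected -= np.log(pl if row.choice == "left" else 1 - pl)
        assert negative_log_likelihood(trials, params) == \
            pytest.approx(expected, abs=1e-10)

    def test_random_null_is_ln_half_per_trial(self, rng):
        design = build_canonical_design("study2")
        trials = generate_preference_trials(design, seed=3)
        trials = trials.assign(
            choice=rng.choice(["left", "right"], len(trials)))
        null_fit, _ = fit_benchmarks(trials)
        assert null_fit.nll_per_trial == pytest.approx(np.log(2), abs=1e-12)
        assert -null_fit.nll_per_trial == pytest.approx(-0.6931, abs=1e-4)

    def test_perfectly_predicted_nll_near_zero(self):
        t = _trials([(0.9, "post_win", 0.1, "post_loss", "left")] * 5)
        params = _valence_params(beta=30.0)
        assert negative_log_likelihood(t, params) / 5 < 1e-6

    def test_empty_raises(self):
        with pytest.raises(ValuationError):
            negative_log_likelihood(_trials([]), _valence_params())


@pytest.fixture(scope="module")
def study2_trials():
    design = build_canonical_design("study2")
    agent = pd.Series({"delta_win": 0.8, "gamma_win": 1.4,
                       "delta_loss": 1.1, "gamma_loss": 0.7, "beta": 6.0})
    return vl.generate_preference_trials_with_choices(design, agent, seed=5)


class TestFitting:
    def test_coin_flip_choices_fit_at_ln2(self, rng):
        design = build_canonical_design("study2")
        trials = generate_preference_trials(design, seed=6)
        trials = trials.assign(
            choice=rng.choice(["left", "right"], len(trials)))
        fit = fit_preference_model(trials, "study2_valence", n_restarts=6)
        assert fit.nll_per_trial == pytest.approx(np.log(2), abs=0.01)

    def test_nesting_full_beats_benchmarks(self, study2_trials):
        fit = fit_preference_model(study2_trials, "study2_valence",
                                   n_restarts=6)
        null_fit, beta_fit = fit_benchmarks(study2_trials)
        assert fit.nll_total <= beta_fit.nll_total + 1e-6
        assert beta_fit.nll_total <= null_fit.nll_total + 1e-6

    def test_too_few_trials_refused(self, study2_trials):
        with pytest.raises(ValuationError, match="refusing"):
            fit_preference_model(study2_trials.head(10), "study2_valence")

    def test_beta_only_recovers_identity_agent(self):
        design = build_canonical_design("study2")
        agent = pd.Series({"delta_win": 1.0, "gamma_win": 1.0,
                           "delta_loss": 1.0, "gamma_loss": 1.0, "beta": 5.0})
        trials = vl.generate_preference_trials_with_choices(design, agent,
                                                            seed=8)
        _, beta_fit = fit_benchmarks(trials)
        assert beta_fit.params.beta == pytest.approx(5.0, rel=0.35)

    def test_sided_fit_recovers_side_asymmetry(self):
        design = build_canonical_design("study1")
        rng = np.random.default_rng(9)
        trials = generate_preference_trials(design, seed=9)
        true = WeightingParams(arms={"left": (0.7, 1.4), "right": (1.2, 0.7)},
                               beta=6.0, variant="study1_sided")
        p_left = choice_probability(trials, true)
        trials = trials.assign(choice=np.where(rng.random(len(trials)) < p_left,
                                               "left", "right"))
        fit = fit_preference_model(trials, "study1_sided", n_restarts=8)
        auc_left = auc_weighting_curve(*fit.params.arms["left"])
        auc_right = auc_weighting_curve(*fit.params.arms["right"])
        assert auc_left > auc_right  # elevation asymmetry recovered


class TestCompareModels:
    def _fit(self, nll_per_trial, n=100):
        return FitResult(_valence_params(), nll_per_trial * n, n)

    def test_identical_lists_t_zero(self):
        fits = [self._fit(x) for x in (0.5, 0.6, 0.7, 0.55)]
        t, df, p = compare_models(fits, fits)
        assert t == 0.0 and df == 3

    def test_matches_t_oracle(self):
        a = [0.50, 0.62, 0.55, 0.58, 0.61]
        b = [0.66, 0.69, 0.60, 0.67, 0.70]
        t, df, p = compare_models([self._fit(x) for x in a],
                                  [self._fit(x) for x in b])
        d = np.array(a) - np.array(b)
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert df == 4

    def test_too_few_subjects(self):
        with pytest.raises(ValuationError):
            compare_models([self._fit(0.5)] * 2, [self._fit(0.6)] * 2)


class TestAuc:
    def test_identity_is_half(self):
        assert auc_weighting_curve(1.0, 1.0) == pytest.approx(0.5, abs=1e-4)

    def test_injected_square_curve(self):
        auc = auc_weighting_curve(1, 1, n_grid=101, weight_fn=lambda p: p ** 2)
        assert auc == pytest.approx(1 / 3, abs=1e-4)

    def test_grid_refinement_converges(self):
        a = auc_weighting_curve(0.7, 1.6, n_grid=101)
        b = auc_weighting_curve(0.7, 1.6, n_grid=1001)
        assert abs(a - b) < 1e-3

    def test_bias_antisymmetry(self):
        fit = FitResult(_valence_params(0.7, 1.5, 1.3, 0.6), 0.0, 1)
        swapped = FitResult(_valence_params(1.3, 0.6, 0.7, 1.5), 0.0, 1)
        b1 = positive_bias_index(fit)
        b2 = positive_bias_index(swapped)
        assert b1.delta_auc == pytest.approx(-b2.delta_auc, abs=1e-12)

    def test_equal_arms_zero_bias(self):
        fit = FitResult(_valence_params(1.1, 0.9, 1.1, 0.9), 0.0, 1)
        assert positive_bias_index(fit).delta_auc == 0.0

    def test_missing_arm_raises(self):
        fit = FitResult(WeightingParams(arms={"win": (1, 1)}, beta=1.0), 0.0, 1)
        with pytest.raises(ValuationError):
            positive_bias_index(fit)


class TestModelFreeBias:
    def test_constructed_counts(self):
        rows = ([(0.9, "post_win", 0.1, "post_loss", "left")] * 7
                + [(0.2, "post_win", 0.8, "post_loss", "right")] * 3)
        assert model_free_bias(_trials(rows)) == 4  # 7 high-win - 3 high-loss

    def test_symmetric_choices_zero(self):
        rows = ([(0.9, "post_win", 0.9, "post_loss", "left")] * 5
                + [(0.9, "post_win", 0.9, "post_loss", "right")] * 5)
        assert model_free_bias(_trials(rows)) == 0

    def test_high_vs_high_counts_chosen_only(self):
        # both options high probability: only the chosen one counts
        rows = [(0.9, "post_win", 0.8, "post_loss", "left")]
        assert model_free_bias(_trials(rows)) == 1


class TestWofLogisticContrast:
    def _subject(self, n11, n10, n01, n00):
        """2x2 layout: x=+1 (win shape high) rows, y=1 (win chosen)."""
        rows = ([(0.9, "post_win", 0.9, "post_neutral", "left")] * n11
                + [(0.9, "post_win", 0.9, "post_neutral", "right")] * n10
                + [(0.1, "post_win", 0.1, "post_neutral", "left")] * n01
                + [(0.1, "post_win", 0.1, "post_neutral", "right")] * n00)
        return _trials(rows)

    def test_matches_log_odds_oracle(self):
        t = self._subject(30, 10, 12, 18)
        coef, flagged = wof_logistic_contrast_subject(t, "win_vs_neutral")
        expected = (np.log(30 / 10) - np.log(12 / 18)) / 2
        assert coef == pytest.approx(expected, abs=1e-12)
        assert not flagged

    def test_matches_statsmodels_logit(self):
        import statsmodels.api as sm
        t = self._subject(25, 15, 10, 20)
        coef, _ = wof_logistic_contrast_subject(t, "win_vs_neutral")
        chose_left = t["choice"] == "left"
        y = chose_left.astype(int)  # win shape always on the left here
        x = np.where(t["left_prob"] > 0.5, 1.0, -1.0)
        res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert coef == pytest.approx(res.params.iloc[1], abs=1e-6)

    def test_separation_flagged(self):
        t = self._subject(20, 0, 5, 15)
        coef, flagged = wof_logistic_contrast_subject(t, "win_vs_neutral")
        assert flagged and np.isfinite(coef)

    def test_group_level_null_centred_on_zero(self, rng):
        n_sig = 0
        reps = 200
        for rep in range(reps):
            subjects = []
            for _ in range(12):
                # choices independent of the probability coding
                n = rng.integers(8, 15, size=4)
                y = rng.binomial(n, 0.5)
                subjects.append(self._subject(y[0], n[0] - y[0],
                                              y[1], n[1] - y[1]))
            res = wof_logistic_contrast(subjects, "win_vs_neutral")
            n_sig += res["p"] < 0.05
        # type-I error ~ alpha: 0.05 +/- 2 SE over the replicates
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(n_sig / reps - 0.05) < 2 * se + 1e-9

    def test_unknown_contrast(self):
        with pytest.raises(ValuationError):
            wof_logistic_contrast_subject(self._subject(5, 5, 5, 5), "bogus")


class TestParameterRecovery:
    def test_reproducible_and_sane(self):
        design = build_canonical_design("study2")
        grid = pd.DataFrame({
            "delta_win": [0.8, 1.2], "gamma_win": [1.4, 0.9],
            "delta_loss": [1.1, 0.8], "gamma_loss": [0.7, 1.2],
            "beta": [6.0, 4.0]})
        r1 = parameter_recovery(design, grid, seed=3, n_restarts=4)
        r2 = parameter_recovery(design, grid, seed=3, n_restarts=4)
        pd.testing.assert_frame_equal(r1["table"], r2["table"])

    def test_near_deterministic_limit_matches_pointwise(self):
        design = build_canonical_design("study2")
        agent = pd.Series({"delta_win": 0.8, "gamma_win": 1.3,
                           "delta_loss": 1.1, "gamma_loss": 0.8, "beta": 30.0})
        trials = vl.generate_preference_trials_with_choices(design, agent,
                                                            seed=4)
        fit = fit_preference_model(trials, "study2_valence", n_restarts=8)
        levels = np.array([0.1, 0.25, 0.4, 0.6, 0.75, 0.9])
        for arm, (d0, g0) in (("win", (0.8, 1.3)), ("loss", (1.1, 0.8))):
            d1, g1 = fit.params.arms[arm]
            err = np.max(np.abs(weight_probability(levels, d1, g1)
                                - weight_probability(levels, d0, g0)))
            assert err < 0.05
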