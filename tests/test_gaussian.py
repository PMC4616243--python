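"""Cumulative-Gaussian fitting, likelihood-ratio testing, and the per-site
shift measures."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import chi2

from rewardstim.gaussian import (
    GaussianFit,
    ShiftMeasure,
    fit_gaussian,
    lr_test,
    pooled_reward_interaction,
    reward_split_effect,
    site_microstim_effect,
)
from rewardstim.simulate import simulate_from_gaussian

from conftest import SEED, make_trials


def _gaussian_site_trials(mu0, mu1, sigma, levels, n_per_cell, seed, cats=("small",)):
    """Site-style table with choices drawn from the two-mean Gaussian truth
    (the independent generative oracle for recovery tests)."""
    rng = np.random.default_rng(seed)
    rows_d, rows_b, rows_c, rows_cat = [], [], [], []
    for lvl in levels:
        for beta in (0, 1):
            for cat in cats:
                p = ndtr((lvl - (mu0 + beta * mu1)) / sigma)
                ch = (rng.random(n_per_cell) < p).astype(int)
                rows_d += [lvl] * n_per_cell
                rows_b += [beta] * n_per_cell
                rows_c += ch.tolist()
                rows_cat += [cat] * n_per_cell
    return make_trials(rows_d, rows_b, rows_c, reward_category=rows_cat)


LEVELS_DEG = (-0.06, -0.03, -0.015, 0.0, 0.015, 0.03, 0.06)


class TestFitGaussian:
    def test_recovers_two_mean_truth(self):
        """Parameters of the two-mean model are recovered from data simulated
        at plausible site magnitudes."""
        df = _gaussian_site_trials(0.01, -0.02, 0.03, LEVELS_DEG, 400, SEED)
        fit = fit_gaussian(df, "1a", n_starts=6, seed=0, stimulus_col="disparity_deg")
        assert fit.converged and fit.identifiable
        assert fit.mu[0] == pytest.approx(0.01, abs=0.004)
        assert fit.mu[1] == pytest.approx(-0.02, abs=0.005)
        assert fit.sigma[0] == pytest.approx(0.03, rel=0.15)

    def test_flat_data_flagged_non_identifiable(self):
        """Responses at exactly one half for every disparity leave the
        threshold unbounded."""
        d, b, c = [], [], []
        for lvl in LEVELS_DEG:
            d += [lvl] * 10
            b += [0] * 10
            c += [1, 0] * 5
        df = make_trials(d, b, c)
        with pytest.warns(UserWarning, match="non-identifiable|diverged"):
            fit = fit_gaussian(df, "1a", n_starts=4, seed=0, stimulus_col="disparity_deg")
        assert not fit.identifiable

    def test_single_disparity_rejected(self):
        df = make_trials([0.02] * 10, [0] * 10, [1, 0] * 5)
        with pytest.raises(ValueError, match="distinct disparities"):
            fit_gaussian(df, "1a", stimulus_col="disparity_deg")

    def test_fit_invariant_to_trial_order(self):
        df = _gaussian_site_trials(0.0, -0.02, 0.03, LEVELS_DEG, 60, SEED)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fit_gaussian(df, "1a", n_starts=4, seed=0, stimulus_col="disparity_deg")
        b = fit_gaussian(shuffled, "1a", n_starts=4, seed=0, stimulus_col="disparity_deg")
        assert a.neg_log_likelihood == pytest.approx(b.neg_log_likelihood, abs=1e-6)
        assert np.allclose(a.mu, b.mu, atol=1e-5)

    def test_rescaling_units_rescales_parameters(self):
        """Fitting in different disparity units gives the same model up to
        the unit change."""
        df = _gaussian_site_trials(0.0, -0.02, 0.03, LEVELS_DEG, 150, SEED)
        scaled = df.assign(disparity_deg=df["disparity_deg"] * 100.0)
        a = fit_gaussian(df, "1a", n_starts=5, seed=0, stimulus_col="disparity_deg")
        b = fit_gaussian(scaled, "1a", n_starts=5, seed=0, stimulus_col="disparity_deg")
        assert b.mu[1] == pytest.approx(100.0 * a.mu[1], rel=0.02)
        assert b.sigma[0] == pytest.approx(100.0 * a.sigma[0], rel=0.02)
        assert a.neg_log_likelihood == pytest.approx(b.neg_log_likelihood, abs=1e-4)

    def test_per_trial_likelihood_equals_grouped(self):
        """The reported likelihood equals a brute-force per-trial Bernoulli
        sum at the fitted parameters."""
        df = _gaussian_site_trials(0.0, -0.02, 0.03, LEVELS_DEG[:5], 30, SEED)
        fit = fit_gaussian(df, "1a", n_starts=4, seed=0, stimulus_col="disparity_deg")
        p = np.clip(
            fit.predict(df["disparity_deg"], 0, df["microstim"].to_numpy()), 1e-9, 1 - 1e-9
        )
        y = df["choice_pref"].to_numpy()
        brute = -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        assert fit.neg_log_likelihood == pytest.approx(brute, abs=1e-6)


class TestLRTest:
    @pytest.mark.parametrize(
        "nll_nested, nll_full, chi",
        [(3045.0, 3034.3, 21.4), (2398.9, 2389.2, 19.4), (3037.9, 3034.3, 7.2), (2394.8, 2389.2, 11.2)],
    )
    def test_chi_arithmetic(self, nll_nested, nll_full, chi):
        res = lr_test(nll_full, nll_nested)
        assert res.chi_stat == pytest.approx(chi, abs=1e-9)

    def test_p_value_from_chi2_df1(self):
        res = lr_test(3034.3, 3037.9)
        assert res.p_value == pytest.approx(chi2.sf(7.2, 1), rel=1e-12)
        assert res.p_value == pytest.approx(0.0073, abs=0.0002)

    def test_equal_likelihoods_give_null(self):
        res = lr_test(100.0, 100.0)
        assert res.chi_stat == 0.0 and res.p_value == 1.0

    def test_small_negative_chi_clamped(self):
        res = lr_test(100.0, 100.0 - 1e-9)
        assert res.chi_stat == 0.0

    def test_mismatched_data_rejected(self):
        a = GaussianFit("1a", np.zeros(4), np.array([1.0, 0, 0]), 10.0, 100, True, 1)
        b = GaussianFit("1b", np.zeros(4), np.array([1.0, 0, 0]), 12.0, 90, True, 1)
        with pytest.raises(ValueError, match="same data"):
            lr_test(a, b)

    def test_non_nested_tags_rejected(self):
        a = GaussianFit("1a", np.zeros(4), np.array([1.0, 0, 0]), 10.0, 100, True, 1)
        b = GaussianFit("2b", np.zeros(4), np.array([1.0, 0, 0]), 12.0, 100, True, 1)
        with pytest.raises(ValueError, match="restriction"):
            lr_test(a, b)

    def test_null_calibration_of_site_test(self):
        """With no true stimulation effect, the two-mean vs single-mean test
        rejects at roughly the nominal 5% rate."""
        rejections = 0
        n_rep = 100
        for i in range(n_rep):
            df = _gaussian_site_trials(0.0, 0.0, 0.03, LEVELS_DEG, 30, 50_000 + i)
            _, lr, _ = site_microstim_effect(df, n_starts=3, seed=0, check_inclusion=False,
                                             stimulus_col="disparity_deg")
            rejections += lr.p_value < 0.05
        assert 0.0 <= rejections / n_rep <= 0.12


class TestShiftMeasures:
    def test_normalized_shift_arithmetic(self):
        fit = GaussianFit("1a", np.array([0.0, -0.1, 0, 0]), np.array([0.2, 0, 0]), 1.0, 10, True, 1)
        m = ShiftMeasure.from_fit(fit)
        assert m.raw_shift == pytest.approx(0.1)
        assert m.normalized_shift == pytest.approx(0.5)
        assert m.toward_pref

    def test_site_effect_recovers_generative_shift(self):
        df = _gaussian_site_trials(0.0, -0.02, 0.03, LEVELS_DEG, 150, SEED)
        shift, lr, fit = site_microstim_effect(df, n_starts=5, seed=0, check_inclusion=False,
                                               stimulus_col="disparity_deg")
        assert shift.toward_pref
        assert shift.raw_shift == pytest.approx(0.02, abs=0.006)
        assert lr.p_value < 0.001

    def test_inclusion_gate(self):
        df = _gaussian_site_trials(0.0, -0.02, 0.03, LEVELS_DEG[:4], 20, SEED)
        with pytest.raises(ValueError, match="inclusion"):
            site_microstim_effect(df)

    def test_reward_split_names_empty_condition(self):
        df = _gaussian_site_trials(0.0, -0.02, 0.03, LEVELS_DEG, 20, SEED)  # all small
        with pytest.raises(ValueError, match="large"):
            reward_split_effect(df, stimulus_col="disparity_deg")

    def test_reward_split_fits_each_condition(self):
        df = _gaussian_site_trials(0.0, -0.02, 0.03, LEVELS_DEG, 80, SEED, cats=("small", "large"))
        out = reward_split_effect(df, n_starts=4, seed=0, stimulus_col="disparity_deg")
        for cond in ("small", "large"):
            assert out[cond][0].reward_condition == cond
            assert out[cond][0].raw_shift == pytest.approx(0.02, abs=0.01)


class TestPooledInteraction:
    def test_single_reward_condition_rejected(self, session_10k):
        sub = session_10k[session_10k["reward_category"] == "small"]
        with pytest.raises(ValueError, match="reward conditions"):
            pooled_reward_interaction(sub, n_starts=2)

    def test_detects_performance_and_shift_modulation(self):
        """Data generated with a steeper large-reward slope and a smaller
        large-reward shift produce the corresponding significant tests."""
        truth = {"mu0": 0.0, "mu1": -0.4, "mu2": 0.0, "mu3": 0.15,
                 "sigma0": 0.5, "sigma1": -0.12, "sigma2": 0.0}
        df = simulate_from_gaussian(truth, 20_000, seed=SEED)
        res = pooled_reward_interaction(df, n_starts=5, seed=0)
        assert res["reward_on_performance"].p_value < 0.01
        assert res["reward_on_shift"].p_value < 0.01
        fit = res["fits"]["2a"]
        assert fit.sigma[1] < 0  # steeper under large reward
        assert fit.mu[3] > 0  # shift magnitude reduced under large reward

    def test_likelihood_dominance(self, session_10k):
        res = pooled_reward_interaction(session_10k, n_starts=3, seed=0)
        full = res["fits"]["2a"].neg_log_likelihood
        for tag in ("2b", "2c"):
            assert res["fits"][tag].neg_log_likelihood >= full - 1e-6

    def test_psychophysics_block_without_stimulation(self):
        truth = {"mu0": 0.0, "sigma0": 0.5, "sigma1": -0.12}
        df = simulate_from_gaussian(truth, 8_000, microstim_fraction=0.0, seed=SEED)
        df["microstim"] = 0
        res = pooled_reward_interaction(df, n_starts=4, seed=0)
        assert res["reward_on_shift"] is None
        assert res["reward_on_performance"].p_value < 0.05
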