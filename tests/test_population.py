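"""Nonparametric population statistics and the correlation battery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rewardstim.population import (
    SITE_EFFECT_COLUMNS,
    correlation,
    fig8_battery,
    lilliefors,
    reward_effect_summary,
    wilcoxon_signrank,
)

from conftest import SEED


def signrank_enumeration_p(diffs: np.ndarray) -> float:
    """Brute-force two-sided sign-rank p: enumerate all 2^n sign assignments
    of the ranks of |d| and count W+ at least as extreme as observed."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_min = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= w_min + 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxonSignrank:
    def test_all_positive_small_samples(self):
        _, p6 = wilcoxon_signrank([1, 2, 3, 4, 5, 6.5], np.zeros(6))
        assert p6 == pytest.approx(2 / 64)
        _, p3 = wilcoxon_signrank([1, 2, 3.5], np.zeros(3))
        assert p3 == pytest.approx(2 / 8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=8)
        while np.unique(np.abs(d)).size < 8 or np.any(d == 0):
            d = rng.normal(0.3, 1.0, size=8)
        _, p = wilcoxon_signrank(d, np.zeros(8))
        assert p == pytest.approx(signrank_enumeration_p(d), abs=1e-12)

    def test_two_sidedness_swap_invariance(self):
        rng = np.random.default_rng(SEED)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        _, p_ab = wilcoxon_signrank(a, b)
        _, p_ba = wilcoxon_signrank(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signrank([1.0, 2.0], [1.0, 2.0])

    def test_exact_and_approx_agree_at_boundary(self):
        """At n = 25 the normal approximation tracks the exact enumeration to
        within a percent on typical data."""
        from scipy.stats import wilcoxon as sp_wilcoxon

        rng = np.random.default_rng(SEED)
        d = rng.normal(0.3, 1.0, size=25)
        p_exact = sp_wilcoxon(d, method="exact").pvalue
        p_approx = sp_wilcoxon(d, method="approx", correction=True).pvalue
        assert abs(p_exact - p_approx) < 0.01


class TestLilliefors:
    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            lilliefors([1.0, 2.0, 3.0])

    def test_detects_right_skew(self):
        x = np.random.default_rng(SEED).standard_normal(100) ** 2
        _, p = lilliefors(x, n_mc=400, seed=0)
        assert p < 0.05

    def test_calibrated_on_gaussian_samples(self):
        """False-rejection rate at the 5% level stays near nominal (scaled
        Monte-Carlo check)."""
        rng = np.random.default_rng(SEED)
        rejections = sum(
            lilliefors(rng.standard_normal(40), n_mc=200, seed=i)[1] < 0.05 for i in range(200)
        )
        assert 0.02 <= rejections / 200 <= 0.09

    def test_agrees_with_table_based_implementation(self):
        """Independent cross-check against the table-based statistic."""
        sm = pytest.importorskip("statsmodels.stats.diagnostic")
        x = np.random.default_rng(SEED).standard_normal(60) + 0.3
        d_ours, p_ours = lilliefors(x, n_mc=3000, seed=1)
        d_sm, p_sm = sm.lilliefors(x, dist="norm")
        assert d_ours == pytest.approx(d_sm, abs=1e-10)
        assert p_ours == pytest.approx(np.clip(p_sm, 0.001, 0.999), abs=0.08)


class TestCorrelation:
    def test_perfect_linear_relation(self):
        r, p = correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation([1, 1, 1], [1, 2, 3])

    def test_matches_textbook_formula(self):
        """n = 10 fixture against the explicit product-moment computation."""
        rng = np.random.default_rng(SEED)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = correlation(x, y)
        hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(hand, abs=1e-12)

    def test_spearman_is_rank_based(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 8.0, 27.0, 64.0, 125.0]  # monotone but curved
        r, _ = correlation(x, y, method="spearman")
        assert r == pytest.approx(1.0)


def _site_rows(n, seed, effect_scale="threshold"):
    """Synthetic per-site summary rows: thresholds grow with eccentricity and
    the raw reward effect is proportional to the threshold (so normalizing
    removes the dependence)."""
    rng = np.random.default_rng(seed)
    ecc = rng.uniform(2, 14, n)
    thr = 0.004 * ecc + rng.normal(0, 0.002, n)
    thr = np.clip(thr, 0.004, None)
    base_norm_shift = 0.8 + rng.normal(0, 0.05, n)
    norm_effect = -0.3 + rng.normal(0, 0.05, n)
    raw_shift = base_norm_shift * thr
    raw_effect = norm_effect * thr
    rows = pd.DataFrame({
        "site_id": [f"s{i}" for i in range(n)],
        "animal_id": ["fle" if i % 2 else "ica" for i in range(n)],
        "eccentricity_deg": ecc,
        "threshold_deg": thr,
        "raw_shift_overall": raw_shift,
        "raw_shift_small": raw_shift * 1.15,
        "raw_shift_large": raw_shift * 1.15 + raw_effect,
        "norm_shift_overall": base_norm_shift,
        "norm_shift_small": base_norm_shift * 1.15,
        "norm_shift_large": base_norm_shift * 1.15 + norm_effect,
        "reward_effect_raw": raw_effect,
        "reward_effect_norm": norm_effect,
        "significant_pref": [True] * n,
        "p_microstim": [0.001] * n,
    })
    return rows[SITE_EFFECT_COLUMNS]


class TestRewardEffectSummary:
    def test_medians_and_signrank(self):
        rows = _site_rows(20, SEED)
        out = reward_effect_summary(rows, "all")
        assert out["norm"]["median_effect"] < 0
        assert out["norm"]["signrank_p"] < 0.01
        assert out["n_sites"] == 20

    def test_identical_conditions_degenerate(self):
        rows = _site_rows(10, SEED)
        rows["raw_shift_large"] = rows["raw_shift_small"]
        rows["norm_shift_large"] = rows["norm_shift_small"]
        with pytest.raises(ValueError, match="zero"):
            reward_effect_summary(rows, "all")

    def test_single_site_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            reward_effect_summary(_site_rows(1, SEED), "all")

    def test_scope_filtering(self):
        rows = _site_rows(12, SEED)
        out = reward_effect_summary(rows, "ica")
        assert out["n_sites"] == 6

    def test_normalization_is_scale_free(self):
        """Multiplying a site's shifts and threshold by a constant leaves its
        normalized effects unchanged."""
        rows = _site_rows(6, SEED)
        scaled = rows.copy()
        for col in ("threshold_deg", "raw_shift_overall", "raw_shift_small", "raw_shift_large",
                    "reward_effect_raw"):
            scaled[col] = scaled[col] * 3.0
        a = reward_effect_summary(rows, "all")["norm"]
        b = reward_effect_summary(scaled, "all")["norm"]
        assert a == b


class TestFig8Battery:
    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="3 sites"):
            fig8_battery(_site_rows(2, SEED))

    def test_raw_effects_correlate_normalized_do_not(self):
        """When the reward effect scales with threshold, the raw-effect
        correlations are significant and normalizing removes them."""
        rows = _site_rows(40, SEED)
        out = fig8_battery(rows, per_animal=False)["pooled"]
        assert out["threshold_vs_eccentricity"]["p"] < 0.01
        assert out["threshold_vs_eccentricity"]["r"] > 0
        assert out["raw_reward_effect_vs_eccentricity"]["p"] < 0.05
        assert out["norm_reward_effect_vs_eccentricity"]["p"] > 0.05
        assert abs(out["norm_reward_effect_vs_eccentricity"]["r"]) < abs(
            out["raw_reward_effect_vs_eccentricity"]["r"]
        )

    def test_per_animal_scopes_present(self):
        out = fig8_battery(_site_rows(12, SEED))
        assert set(out) == {"pooled", "fle", "ica"}
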