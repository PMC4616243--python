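"""Population-level statistics: site-by-site reward-effect summaries,
nonparametric tests, the Monte-Carlo normality check, and the correlation
battery relating thresholds, eccentricity and stimulation effects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gaussian import reward_split_effect, site_microstim_effect
from .trial_data import inclusion_filter


def wilcoxon_signrank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon sign-rank test on paired values.

    Zero differences are dropped before ranking.  With n <= 25 pairs and no
    tied magnitudes the exact null enumeration is used; otherwise the normal
    approximation with continuity and tie corrections.  Returns (W, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: no information")
    if d.size < 2:
        raise ValueError("need at least 2 non-zero differences")
    no_ties = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and no_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def lilliefors(values, n_mc: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Composite-normality test: KS distance of the standardized sample from
    N(0, 1), with the null distribution of the statistic obtained by Monte
    Carlo (mean and s.d. re-estimated on every resample).  Returns (D, p).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 values")

    def _stat(sample: np.ndarray) -> float:
        z = (sample - sample.mean()) / sample.std(ddof=1)
        return float(stats.kstest(z, "norm").statistic)

    d_obs = _stat(x)
    rng = np.random.default_rng(seed)
    null = np.array([_stat(rng.standard_normal(n)) for _ in range(n_mc)])
    p = (1.0 + np.sum(null >= d_obs)) / (n_mc + 1.0)
    return d_obs, float(p)


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (Pearson product-moment or
    Spearman rank)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


SITE_EFFECT_COLUMNS = [
    "site_id", "animal_id", "eccentricity_deg", "threshold_deg",
    "raw_shift_overall", "raw_shift_small", "raw_shift_large",
    "norm_shift_overall", "norm_shift_small", "norm_shift_large",
    "reward_effect_raw", "reward_effect_norm",
    "significant_pref", "p_microstim",
]


def build_site_effects(
    trials: pd.DataFrame,
    sites: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    apply_inclusion: bool = True,
) -> pd.DataFrame:
    """Per-site microstimulation shifts, reward-split shifts and significance.

    Fits the two-mean Gaussian per site on raw disparities (overall, and
    separately per reward condition, normalizing each shift by that
    condition's threshold), and flags sites whose shift is significant and
    toward PREF.  Signed shifts are positive toward PREF.
    """
    ecc = dict(zip(sites["site_id"].astype(str), sites["eccentricity_deg"].astype(float)))
    if apply_inclusion:
        report = inclusion_filter(trials)
        keep = set(report.index[report["passed"]])
        trials = trials[trials["site_id"].astype(str).isin(keep)]
    rows = []
    for site_id, sub in trials.groupby("site_id", sort=True):
        shift, lr, fit = site_microstim_effect(
            sub, n_starts=n_starts, seed=seed, check_inclusion=False, stimulus_col="disparity_deg"
        )
        split = reward_split_effect(sub, n_starts=n_starts, seed=seed, stimulus_col="disparity_deg")
        sign = 1.0 if shift.toward_pref else -1.0
        raw_small = split["small"][0].raw_shift * (1.0 if split["small"][0].toward_pref else -1.0)
        raw_large = split["large"][0].raw_shift * (1.0 if split["large"][0].toward_pref else -1.0)
        norm_small = split["small"][0].normalized_shift * (1.0 if split["small"][0].toward_pref else -1.0)
        norm_large = split["large"][0].normalized_shift * (1.0 if split["large"][0].toward_pref else -1.0)
        rows.append({
            "site_id": str(site_id),
            "animal_id": str(sub["animal_id"].iloc[0]),
            "eccentricity_deg": ecc.get(str(site_id), np.nan),
            "threshold_deg": shift.threshold,
            "raw_shift_overall": shift.raw_shift * sign,
            "raw_shift_small": raw_small,
            "raw_shift_large": raw_large,
            "norm_shift_overall": shift.normalized_shift * sign,
            "norm_shift_small": norm_small,
            "norm_shift_large": norm_large,
            "reward_effect_raw": raw_large - raw_small,
            "reward_effect_norm": norm_large - norm_small,
            "significant_pref": bool(lr.p_value < 0.05 and shift.toward_pref),
            "p_microstim": lr.p_value,
        })
    return pd.DataFrame(rows, columns=SITE_EFFECT_COLUMNS)


def reward_effect_summary(site_rows: pd.DataFrame, scope: str = "all") -> dict:
    """Median shifts per reward condition and sign-rank tests (raw and
    normalized) over sites in scope.

    scope: ``all`` | ``significant_pref`` | an animal_id.
    """
    df = site_rows
    if scope == "significant_pref":
        df = df[df["significant_pref"]]
    elif scope != "all":
        df = df[df["animal_id"] == scope]
    if len(df) < 2:
        raise ValueError(f"scope {scope!r} has fewer than 2 sites")
    out = {"scope": scope, "n_sites": int(len(df))}
    for kind in ("raw", "norm"):
        large = df[f"{kind}_shift_large"].to_numpy()
        small = df[f"{kind}_shift_small"].to_numpy()
        W, p = wilcoxon_signrank(large, small)
        out[kind] = {
            "median_small": float(np.median(small)),
            "median_large": float(np.median(large)),
            "median_effect": float(np.median(large - small)),
            "signrank_W": W,
            "signrank_p": p,
        }
    return out


_FIG8_PAIRS = {
    "threshold_vs_eccentricity": ("eccentricity_deg", "threshold_deg"),
    "raw_shift_vs_threshold": ("threshold_deg", "raw_shift_overall"),
    "raw_reward_effect_vs_eccentricity": ("eccentricity_deg", "reward_effect_raw"),
    "raw_reward_effect_vs_raw_shift": ("raw_shift_overall", "reward_effect_raw"),
    "norm_reward_effect_vs_eccentricity": ("eccentricity_deg", "reward_effect_norm"),
    "norm_reward_effect_vs_norm_shift": ("norm_shift_overall", "reward_effect_norm"),
}


def fig8_battery(site_rows: pd.DataFrame, method: str = "pearson", per_animal: bool = True) -> dict:
    """The six-correlation battery over site summaries: threshold vs
    eccentricity, raw shift vs threshold, and the reward effect (raw and
    normalized) against eccentricity and overall shift; pooled and, when
    requested, per animal."""
    if len(site_rows) < 3:
        raise ValueError("need at least 3 sites")
    scopes = {"pooled": site_rows}
    if per_animal:
        for animal, sub in site_rows.groupby("animal_id"):
            scopes[str(animal)] = sub
    out: dict = {}
    for scope_name, df in scopes.items():
        res = {}
        for name, (xcol, ycol) in _FIG8_PAIRS.items():
            try:
                r, p = correlation(df[xcol], df[ycol], method=method)
            except ValueError as exc:
                warnings.warn(f"{scope_name}/{name}: {exc}", stacklevel=2)
                r, p = float("nan"), float("nan")
            res[name] = {"r": r, "p": p, "n": int(len(df))}
        out[scope_name] = res
    return out
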