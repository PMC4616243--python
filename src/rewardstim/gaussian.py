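"""Cumulative-Gaussian psychometric models and nested likelihood-ratio tests.

Two model families over PREF-choice probability as a function of signed
disparity C (positive toward the stimulated site's preferred rotation):

* per-site two-mean family -- P(C) = Phi((C - (mu0 + beta*mu1)) / sigma), a
  pair of cumulative Gaussians sharing sigma whose means differ by the
  stimulation flag beta (tags ``1a`` full / ``1b`` single-mean);
* pooled interaction family -- mean mu0 + beta*mu1 + alpha*mu2 + alpha*beta*mu3
  and s.d. sigma0 + alpha*sigma1 + beta*sigma2, where alpha flags large-reward
  trials (tags ``2a`` full, ``2b`` sigma1 frozen, ``2c`` mu3 frozen).

All fits are per-trial Bernoulli maximum likelihood (evaluated on grouped
cells, which is identical), multi-start.  The microstimulation effect of a
site is the fitted mean offset mu1 expressed as an equivalent disparity: with
C positive toward PREF, a PREF-ward bias is mu1 < 0 and is reported as a
positive shift toward PREF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

from ._mle import CellData, MLEResult, group_trials, maximize, neg_log_likelihood, penalty
from .trial_data import inclusion_filter

PARAM_NAMES = ("mu0", "mu1", "mu2", "mu3", "sigma0", "sigma1", "sigma2")

_FREE_BY_TAG = {
    "1a": ("mu0", "mu1", "sigma0"),
    "1b": ("mu0", "sigma0"),
    "2a": PARAM_NAMES,
    "2b": tuple(n for n in PARAM_NAMES if n != "sigma1"),
    "2c": tuple(n for n in PARAM_NAMES if n != "mu3"),
}

# Restriction structure used to sanity-check nesting in lr_test (both the
# Gaussian family and the accumulation family use the same test).
NESTED_PAIRS = {("1a", "1b"), ("2a", "2b"), ("2a", "2c"), ("3a", "3b"), ("3a", "3c")}


@dataclass
class GaussianFit:
    """Fitted cumulative-Gaussian psychometric model."""

    model_tag: str
    mu: np.ndarray  # (mu0, mu1, mu2, mu3); frozen entries fixed at 0
    sigma: np.ndarray  # (sigma0, sigma1, sigma2); frozen entries fixed at 0
    neg_log_likelihood: float
    n_trials: int
    converged: bool
    n_starts: int
    identifiable: bool = True
    stimulus_col: str = "C"

    def params(self) -> dict[str, float]:
        out = {n: float(v) for n, v in zip(PARAM_NAMES[:4], self.mu)}
        out.update({n: float(v) for n, v in zip(PARAM_NAMES[4:], self.sigma)})
        return out

    def predict(self, C, alpha=0, beta=0) -> np.ndarray:
        C = np.asarray(C, dtype=float)
        mu0, mu1, mu2, mu3 = self.mu
        s0, s1, s2 = self.sigma
        mean = mu0 + beta * mu1 + alpha * mu2 + alpha * beta * mu3
        sd = s0 + alpha * s1 + beta * s2
        return ndtr((C - mean) / sd)

    def invert(self, p, alpha=0, beta=0) -> np.ndarray:
        """Disparity at which the fitted curve attains probability ``p``."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("can only invert probabilities strictly inside (0, 1)")
        mu0, mu1, mu2, mu3 = self.mu
        s0, s1, s2 = self.sigma
        mean = mu0 + beta * mu1 + alpha * mu2 + alpha * beta * mu3
        sd = s0 + alpha * s1 + beta * s2
        if not self.identifiable or sd <= 0:
            raise ValueError("fit is flat/non-identifiable; cannot invert")
        return mean + sd * ndtri(p)


@dataclass
class LRResult:
    """Chi-square likelihood-ratio comparison of nested model fits (df = 1)."""

    neg_logL_full: float
    neg_logL_nested: float
    df: int = 1
    chi_stat: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        chi = 2.0 * (self.neg_logL_nested - self.neg_logL_full)
        if chi < 0:
            if chi < -1e-6:
                warnings.warn(
                    f"nested model out-fitted the full model (chi = {chi:.3g}); clamping to 0",
                    stacklevel=2,
                )
            chi = 0.0
        self.chi_stat = chi
        self.p_value = float(chi2.sf(chi, self.df))


@dataclass
class ShiftMeasure:
    """Microstimulation-induced horizontal shift for one fit.

    ``raw_shift`` is the magnitude |mu1| of the equivalent disparity;
    ``toward_pref`` records whether the bias was toward the PREF direction
    (mu1 < 0 given the sign convention).  ``normalized_shift`` divides by the
    psychometric threshold (fitted sigma) of the same condition.
    """

    raw_shift: float
    threshold: float
    normalized_shift: float
    reward_condition: str  # all | small | large
    toward_pref: bool

    @classmethod
    def from_fit(cls, fit: GaussianFit, reward_condition: str = "all") -> "ShiftMeasure":
        mu1 = float(fit.mu[1])
        sigma = float(fit.sigma[0])
        if sigma <= 0:
            raise ValueError("threshold must be > 0")
        return cls(
            raw_shift=abs(mu1),
            threshold=sigma,
            normalized_shift=abs(mu1) / sigma,
            reward_condition=reward_condition,
            toward_pref=mu1 < 0,
        )


def _theta_to_params(theta: np.ndarray, free: tuple[str, ...], log_sigma0: bool) -> dict[str, float]:
    params = dict.fromkeys(PARAM_NAMES, 0.0)
    for name, value in zip(free, theta):
        params[name] = float(value)
    if log_sigma0:
        params["sigma0"] = float(np.exp(params["sigma0"]))
    return params


def _cell_probability(params: dict[str, float], cells: CellData) -> tuple[np.ndarray, float]:
    mean = (
        params["mu0"]
        + cells.beta * params["mu1"]
        + cells.alpha * params["mu2"]
        + cells.alpha * cells.beta * params["mu3"]
    )
    sd = params["sigma0"] + cells.alpha * params["sigma1"] + cells.beta * params["sigma2"]
    min_sd = float(np.min(sd))
    if min_sd <= 0:
        return np.full_like(mean, 0.5), min_sd
    return ndtr((cells.C - mean) / sd), min_sd


def fit_gaussian(
    trials: pd.DataFrame,
    model_tag: str,
    n_starts: int = 10,
    seed: int = 0,
    stimulus_col: str | None = None,
    extra_starts: list[dict[str, float]] | None = None,
) -> GaussianFit:
    """Maximum-likelihood fit of one cumulative-Gaussian model variant.

    ``stimulus_col`` defaults to normalized disparity ``C`` when present,
    otherwise raw ``disparity_deg``.  Degenerate data (all choices identical)
    yields a fit flagged non-identifiable with a warning rather than an error.
    """
    if model_tag not in _FREE_BY_TAG:
        raise ValueError(f"unknown model tag {model_tag!r}")
    if stimulus_col is None:
        stimulus_col = "C" if "C" in trials.columns else "disparity_deg"
    pooled_family = model_tag.startswith("2")
    cells = group_trials(
        trials,
        stimulus_col=stimulus_col,
        alpha_col="reward_category" if pooled_family else None,
    )
    if np.unique(cells.C).size < 2:
        raise ValueError("need at least 2 distinct disparities to fit a psychometric function")

    free = list(_FREE_BY_TAG[model_tag])
    if pooled_family:
        if np.unique(cells.alpha).size < 2:
            raise ValueError("pooled reward models need both reward conditions present")
        if np.unique(cells.beta).size < 2:
            # Psychophysics-only blocks: collapse the stimulation terms.
            free = [n for n in free if n not in ("mu1", "mu3", "sigma2")]
    free = tuple(free)
    log_sigma0 = not pooled_family  # single-sigma models enforce positivity on a log scale

    degenerate = bool(cells.y.sum() == 0 or cells.y.sum() == cells.n.sum())
    if degenerate:
        warnings.warn("all choices identical: psychometric fit is non-identifiable", stacklevel=2)

    span = float(cells.C.max() - cells.C.min())

    def objective(theta: np.ndarray) -> float:
        params = _theta_to_params(theta, free, log_sigma0)
        p, min_sd = _cell_probability(params, cells)
        if min_sd <= 0:
            return penalty(-min_sd)
        return neg_log_likelihood(p, cells)

    lo, hi = [], []
    for name in free:
        if name == "sigma0":
            if log_sigma0:
                lo.append(np.log(0.1 * span))
                hi.append(np.log(10.0 * span))
            else:
                lo.append(0.05 * span)
                hi.append(1.5 * span)
        elif name in ("sigma1", "sigma2"):
            lo.append(-0.2 * span)
            hi.append(0.2 * span)
        else:  # means and their increments stay within the observed span
            lo.append(-0.5 * span)
            hi.append(0.5 * span)

    extras = []
    for start in extra_starts or []:
        theta = []
        for name in free:
            v = start.get(name, 0.0)
            if name == "sigma0" and log_sigma0:
                v = np.log(max(v, 1e-6))
            theta.append(v)
        extras.append(np.asarray(theta, dtype=float))

    res: MLEResult = maximize(
        objective, np.array(lo), np.array(hi), n_starts=n_starts, seed=seed, extra_starts=extras
    )
    params = _theta_to_params(res.theta, free, log_sigma0)

    identifiable = not degenerate
    if params["sigma0"] > 50.0 * span:
        warnings.warn("fitted threshold diverged (flat data?); flagging non-identifiable", stacklevel=2)
        identifiable = False

    return GaussianFit(
        model_tag=model_tag,
        mu=np.array([params[n] for n in PARAM_NAMES[:4]]),
        sigma=np.array([params[n] for n in PARAM_NAMES[4:]]),
        neg_log_likelihood=res.neg_log_likelihood,
        n_trials=cells.n_trials,
        converged=res.converged,
        n_starts=res.n_starts,
        identifiable=identifiable,
        stimulus_col=stimulus_col,
    )


def lr_test(full, nested) -> LRResult:
    """Chi-square likelihood-ratio test of a full model against a one-parameter
    restriction fitted on the same data.

    Accepts fitted model objects (with ``neg_log_likelihood``/``n_trials``) or
    bare negative log-likelihoods.
    """
    if hasattr(full, "neg_log_likelihood"):
        if hasattr(nested, "n_trials") and full.n_trials != nested.n_trials:
            raise ValueError("full and nested fits are not on the same data (n_trials differ)")
        tags = (getattr(full, "model_tag", None), getattr(nested, "model_tag", None))
        if all(tags) and tags not in NESTED_PAIRS:
            raise ValueError(f"{tags[1]} is not a one-parameter restriction of {tags[0]}")
        return LRResult(full.neg_log_likelihood, nested.neg_log_likelihood)
    return LRResult(float(full), float(nested))


def site_microstim_effect(
    trials: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    check_inclusion: bool = True,
    stimulus_col: str | None = None,
) -> tuple[ShiftMeasure, LRResult, GaussianFit]:
    """Per-site microstimulation effect: two-mean vs single-mean Gaussian fits.

    Returns the shift (|mu1| as equivalent disparity, normalized by the fitted
    threshold), the significance test and the full fit.
    """
    if check_inclusion:
        report = inclusion_filter(trials)
        failing = report.index[~report["passed"]].tolist()
        if failing:
            reasons = report.loc[failing, "reason"].tolist()
            raise ValueError(f"site(s) fail the inclusion criterion: {failing} ({reasons})")
    nested = fit_gaussian(trials, "1b", n_starts=n_starts, seed=seed, stimulus_col=stimulus_col)
    full = fit_gaussian(
        trials, "1a", n_starts=n_starts, seed=seed, stimulus_col=stimulus_col,
        extra_starts=[nested.params()],
    )
    refined = fit_gaussian(trials, "1b", n_starts=0, seed=seed, stimulus_col=stimulus_col,
                           extra_starts=[full.params()])
    if refined.neg_log_likelihood < nested.neg_log_likelihood:
        nested = refined
    return ShiftMeasure.from_fit(full, "all"), lr_test(full, nested), full


def reward_split_effect(
    trials: pd.DataFrame, n_starts: int = 10, seed: int = 0, stimulus_col: str | None = None
) -> dict[str, tuple[ShiftMeasure, GaussianFit]]:
    """Refit the two-mean model separately on small- and large-reward trials.

    Each condition's shift is normalized by that condition's own threshold.
    """
    out: dict[str, tuple[ShiftMeasure, GaussianFit]] = {}
    for condition in ("small", "large"):
        sub = trials[trials["reward_category"] == condition]
        if len(sub) == 0:
            raise ValueError(f"reward condition {condition!r} is empty")
        if sub[stimulus_col or ("C" if "C" in sub.columns else "disparity_deg")].nunique() < 2:
            raise ValueError(f"reward condition {condition!r} has < 2 distinct disparities")
        fit = fit_gaussian(sub, "1a", n_starts=n_starts, seed=seed, stimulus_col=stimulus_col)
        out[condition] = (ShiftMeasure.from_fit(fit, condition), fit)
    return out


def pooled_reward_interaction(
    trials: pd.DataFrame, n_starts: int = 10, seed: int = 0
) -> dict:
    """Reward x stimulation interaction on pooled, normalized trials.

    Fits the full interaction model and its two one-parameter restrictions,
    then tests reward-on-performance (full vs sigma1 frozen) and
    reward-on-stimulation-shift (full vs mu3 frozen).
    """
    if "C" not in trials.columns:
        raise ValueError("pooled fits need the normalized disparity column 'C'")
    fits: dict[str, GaussianFit] = {}
    has_stim = trials["microstim"].nunique() > 1
    fits["2b"] = fit_gaussian(trials, "2b", n_starts=n_starts, seed=seed)
    if has_stim:
        fits["2c"] = fit_gaussian(trials, "2c", n_starts=n_starts, seed=seed)
    extras = [fits[t].params() for t in fits]
    fits["2a"] = fit_gaussian(trials, "2a", n_starts=n_starts, seed=seed, extra_starts=extras)
    # Re-polish restrictions from the full optimum so neither side of the
    # likelihood-ratio comparison is short-changed by local minima.
    for tag in list(fits):
        if tag == "2a":
            continue
        refined = fit_gaussian(trials, tag, n_starts=0, seed=seed,
                               extra_starts=[fits["2a"].params()])
        if refined.neg_log_likelihood < fits[tag].neg_log_likelihood:
            fits[tag] = refined
    return {
        "fits": fits,
        "reward_on_performance": lr_test(fits["2a"], fits["2b"]),
        # Without a stimulation condition there is no shift term to test.
        "reward_on_shift": lr_test(fits["2a"], fits["2c"]) if has_stim else None,
    }
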