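"""Bounded-accumulation logistic choice model and its reward-modulation tests.

The model is a logistic read-out of a one-dimensional drift-diffusion process
with fixed viewing duration:

    P_PREF(C) = 1 / (1 + exp(-[(B0 + a*B1) * ((k0 + a*k1 + b*k2) * C + b)
                               + x0 + a*x1]))

where C is normalized disparity (positive toward PREF), a flags large-reward
trials and b flags microstimulated trials.  k terms are stimulus sensitivity
(drift per unit disparity), B terms the distance-to-bound / accumulation gain,
and x terms a null-direction choice bias.  Electrically injected evidence has
magnitude fixed at 1 inside the bracket, so its behavioural size in disparity
units is 1/k -- which is what dissociates a reward effect on k (shift shrinks)
from one on B (shift unchanged).

Model tags: ``3a`` full; ``3b`` freezes k1 = 0 (sensitivity not modulated by
reward); ``3c`` freezes B1 = 0 (bound not modulated by reward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._mle import group_trials, maximize, neg_log_likelihood
from .gaussian import GaussianFit, LRResult, lr_test

ACCUM_PARAM_NAMES = ("k0", "k1", "k2", "B0", "B1", "x0", "x1")

_FROZEN_BY_TAG = {"3a": (), "3b": ("k1",), "3c": ("B1",)}

ACCUM_NESTED_PAIRS = {("3a", "3b"), ("3a", "3c")}


def accumulation_probability(params: dict[str, float], C, alpha, beta) -> np.ndarray:
    """Evaluate the choice model at parameter dict and condition arrays."""
    C = np.asarray(C, dtype=float)
    k_eff = params["k0"] + alpha * params["k1"] + beta * params["k2"]
    B_eff = params["B0"] + alpha * params["B1"]
    x_eff = params["x0"] + alpha * params["x1"]
    return expit(B_eff * (k_eff * C + beta) + x_eff)


@dataclass
class AccumulationFit:
    """Fitted bounded-accumulation choice model."""

    model_tag: str
    k: np.ndarray  # (k0, k1, k2); frozen entries fixed 0
    B: np.ndarray  # (B0, B1)
    x: np.ndarray  # (x0, x1)
    neg_log_likelihood: float
    n_trials: int
    converged: bool
    n_starts: int
    gain_positive: bool = True  # effective gain B0 + alpha*B1 > 0 in all cells

    def params(self) -> dict[str, float]:
        return {
            "k0": float(self.k[0]), "k1": float(self.k[1]), "k2": float(self.k[2]),
            "B0": float(self.B[0]), "B1": float(self.B[1]),
            "x0": float(self.x[0]), "x1": float(self.x[1]),
        }

    def predict(self, C, alpha=0, beta=0) -> np.ndarray:
        return accumulation_probability(self.params(), np.asarray(C, dtype=float), alpha, beta)

    def invert(self, p, alpha=0, beta=0) -> np.ndarray:
        """Disparity at which the fitted curve attains probability ``p``."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("can only invert probabilities strictly inside (0, 1)")
        pr = self.params()
        k_eff = pr["k0"] + alpha * pr["k1"] + beta * pr["k2"]
        B_eff = pr["B0"] + alpha * pr["B1"]
        x_eff = pr["x0"] + alpha * pr["x1"]
        if k_eff == 0 or B_eff == 0:
            raise ValueError("flat fit (zero effective sensitivity or gain); cannot invert")
        return ((logit(p) - x_eff) / B_eff - beta) / k_eff


@dataclass
class ModulationRow:
    """One parameter's reward-modulation summary in the machine-readable report."""

    parameter: str  # "k" or "B"
    estimate_small: float
    estimate_large: float
    percent_change: float
    neg_logL_frozen: float
    neg_logL_full: float
    chi_stat: float
    p_value: float


@dataclass
class ModulationTable:
    rows: dict[str, ModulationRow]
    fits: dict[str, AccumulationFit]

    def to_dict(self) -> dict:
        return {
            name: {
                "estimate_small": row.estimate_small,
                "estimate_large": row.estimate_large,
                "percent_change": row.percent_change,
                "neg_logL_frozen": row.neg_logL_frozen,
                "neg_logL_full": row.neg_logL_full,
                "chi_stat": row.chi_stat,
                "p_value": row.p_value,
            }
            for name, row in self.rows.items()
        }


def percent_change(small: float, large: float) -> float:
    """Percent change of an estimate from the small- to the large-reward
    condition: 100 * (large - small) / small."""
    if small == 0:
        raise ValueError("small-reward estimate is zero; percent change undefined")
    return 100.0 * (large - small) / small


def fit_accumulation(
    trials: pd.DataFrame,
    model_tag: str = "3a",
    n_starts: int = 10,
    seed: int = 0,
    extra_starts: list[dict[str, float]] | None = None,
) -> AccumulationFit:
    """Bernoulli MLE of the bounded-accumulation choice model on pooled,
    normalized trials.  Requires both stimulation conditions, and both reward
    conditions for tags that test reward terms."""
    if model_tag not in _FROZEN_BY_TAG:
        raise ValueError(f"unknown model tag {model_tag!r}")
    if "C" not in trials.columns:
        raise ValueError("accumulation fits need the normalized disparity column 'C'")
    cells = group_trials(trials, stimulus_col="C")
    if np.unique(cells.beta).size < 2:
        raise ValueError("both stimulation conditions must be present")
    if np.unique(cells.alpha).size < 2:
        raise ValueError("both reward conditions must be present")
    if np.all(cells.C == 0):
        raise ValueError("disparity column is all zero: sensitivity is non-identifiable")

    frozen = _FROZEN_BY_TAG[model_tag]
    free = tuple(n for n in ACCUM_PARAM_NAMES if n not in frozen)

    def unpack(theta: np.ndarray) -> dict[str, float]:
        params = dict.fromkeys(ACCUM_PARAM_NAMES, 0.0)
        for name, value in zip(free, theta):
            params[name] = float(value)
        return params

    def objective(theta: np.ndarray) -> float:
        params = unpack(theta)
        p = accumulation_probability(params, cells.C, cells.alpha, cells.beta)
        return neg_log_likelihood(p, cells)

    ranges = {
        "k0": (0.3, 6.0), "k1": (-2.0, 3.0), "k2": (-1.0, 2.0),
        "B0": (0.3, 5.0), "B1": (-2.0, 2.0), "x0": (-2.0, 2.0), "x1": (-2.0, 2.0),
    }
    # Scale sensitivity ranges to the stimulus span (defaults assume |C| <= 1).
    span = float(np.max(np.abs(cells.C)))
    if span > 0 and not np.isclose(span, 1.0):
        for name in ("k0", "k1", "k2"):
            lo, hi = ranges[name]
            ranges[name] = (lo / span, hi / span)
    lo = np.array([ranges[n][0] for n in free])
    hi = np.array([ranges[n][1] for n in free])

    extras = []
    for start in extra_starts or []:
        extras.append(np.array([start.get(n, 0.0) for n in free], dtype=float))

    res = maximize(objective, lo, hi, n_starts=n_starts, seed=seed, extra_starts=extras)
    if not res.converged:
        raise RuntimeError(
            f"accumulation fit ({model_tag}) failed to converge after {res.n_starts} starts "
            f"(best neg logL = {res.neg_log_likelihood:.6g})"
        )
    params = unpack(res.theta)

    gains = params["B0"] + np.unique(cells.alpha) * params["B1"]
    gain_positive = bool(np.all(gains > 0))
    if not gain_positive:
        warnings.warn("effective accumulation gain <= 0 in some reward condition", stacklevel=2)

    return AccumulationFit(
        model_tag=model_tag,
        k=np.array([params["k0"], params["k1"], params["k2"]]),
        B=np.array([params["B0"], params["B1"]]),
        x=np.array([params["x0"], params["x1"]]),
        neg_log_likelihood=res.neg_log_likelihood,
        n_trials=cells.n_trials,
        converged=res.converged,
        n_starts=res.n_starts,
        gain_positive=gain_positive,
    )


def analytic_shift(fit: AccumulationFit | dict[str, float], alpha: int = 0) -> float:
    """Closed-form microstimulation-induced PSE shift of the fitted curve.

    PSE(non-stim) = -x_eff / (B_eff * k_ns) with k_ns = k0 + alpha*k1;
    PSE(stim)     = -(x_eff / B_eff + 1) / (k_ns + k2);
    shift = PSE(non-stim) - PSE(stim).  With x_eff = 0 and k2 = 0 this is
    exactly 1/k_ns, independent of the bound term -- the core dissociation.
    """
    params = fit.params() if hasattr(fit, "params") else dict(fit)
    k_ns = params["k0"] + alpha * params["k1"]
    k_stim = k_ns + params["k2"]
    B_eff = params["B0"] + alpha * params["B1"]
    x_eff = params["x0"] + alpha * params["x1"]
    if k_ns == 0 or k_stim == 0:
        raise ValueError("zero effective sensitivity: PSE undefined")
    if B_eff == 0:
        raise ValueError("zero effective gain: PSE undefined")
    pse_nonstim = -x_eff / (B_eff * k_ns)
    pse_stim = -(x_eff / B_eff + 1.0) / k_stim
    return pse_nonstim - pse_stim


def _refine_nested(trials, nested_fit, full_fit, seed) -> AccumulationFit:
    """Re-polish a nested fit from the full fit's projection so neither side
    of the likelihood-ratio comparison is short-changed by local minima."""
    refined = fit_accumulation(
        trials, nested_fit.model_tag, n_starts=0, seed=seed, extra_starts=[full_fit.params()]
    )
    return refined if refined.neg_log_likelihood < nested_fit.neg_log_likelihood else nested_fit


def nested_comparison(
    trials: pd.DataFrame, nested_tag: str, n_starts: int = 10, seed: int = 0
) -> tuple[AccumulationFit, AccumulationFit, LRResult]:
    """Fit the full model and one restriction with mutual warm starts;
    returns (full, nested, test)."""
    nested = fit_accumulation(trials, nested_tag, n_starts=n_starts, seed=seed)
    full = fit_accumulation(
        trials, "3a", n_starts=n_starts, seed=seed, extra_starts=[nested.params()]
    )
    nested = _refine_nested(trials, nested, full, seed)
    return full, nested, lr_test(full, nested)


def reward_modulation_report(
    trials: pd.DataFrame, n_starts: int = 10, seed: int = 0
) -> ModulationTable:
    """Fit the full model and both one-parameter restrictions; report per
    parameter (k, B) the small/large estimates, percent change, and the
    likelihood-ratio comparison."""
    fit_3b = fit_accumulation(trials, "3b", n_starts=n_starts, seed=seed)
    fit_3c = fit_accumulation(trials, "3c", n_starts=n_starts, seed=seed)
    fit_3a = fit_accumulation(
        trials, "3a", n_starts=n_starts, seed=seed,
        extra_starts=[fit_3b.params(), fit_3c.params()],
    )
    fit_3b = _refine_nested(trials, fit_3b, fit_3a, seed)
    fit_3c = _refine_nested(trials, fit_3c, fit_3a, seed)
    p = fit_3a.params()
    rows = {}
    for name, frozen_fit in (("k", fit_3b), ("B", fit_3c)):
        small = p[f"{name}0"]
        large = p[f"{name}0"] + p[f"{name}1"]
        lr = lr_test(fit_3a, frozen_fit)
        rows[name] = ModulationRow(
            parameter=name,
            estimate_small=small,
            estimate_large=large,
            percent_change=percent_change(small, large),
            neg_logL_frozen=frozen_fit.neg_log_likelihood,
            neg_logL_full=fit_3a.neg_log_likelihood,
            chi_stat=lr.chi_stat,
            p_value=lr.p_value,
        )
    return ModulationTable(rows=rows, fits={"3a": fit_3a, "3b": fit_3b, "3c": fit_3c})


def qq_compare(
    trials: pd.DataFrame, gaussian_fit: GaussianFit, accumulation_fit: AccumulationFit
) -> dict:
    """Quantile-quantile comparison of both fitted models against the data.

    For every (C, alpha, beta) cell the observed PREF proportion is pushed
    back through each fitted psychometric function to the disparity that would
    produce it; cells at exactly 0 or 1 cannot be inverted and are omitted
    (their count is reported).  Pearson r is returned for data-vs-model and
    model-vs-model pairings.
    """
    cells = group_trials(trials, stimulus_col="C")
    prop = cells.y / cells.n
    keep = (prop > 0) & (prop < 1)
    n_omitted = int((~keep).sum())
    C_obs = cells.C[keep]
    a, b, p = cells.alpha[keep], cells.beta[keep], prop[keep]
    C_gauss = np.array([float(gaussian_fit.invert(pi, ai, bi)) for pi, ai, bi in zip(p, a, b)])
    C_accum = np.array([float(accumulation_fit.invert(pi, ai, bi)) for pi, ai, bi in zip(p, a, b)])
    table = pd.DataFrame(
        {"C_observed": C_obs, "alpha": a, "beta": b, "proportion_pref": p,
         "C_gaussian": C_gauss, "C_accumulation": C_accum}
    )

    def _r(u, v):
        if len(u) < 2 or np.std(u) == 0 or np.std(v) == 0:
            return float("nan")
        return float(np.corrcoef(u, v)[0, 1])

    return {
        "table": table,
        "n_omitted": n_omitted,
        "r_data_gaussian": _r(C_obs, C_gauss),
        "r_data_accumulation": _r(C_obs, C_accum),
        "r_model_model": _r(C_gauss, C_accum),
    }
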