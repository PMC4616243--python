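"""Shared Bernoulli maximum-likelihood machinery for the psychometric models.

Trials are grouped into (stimulus, reward, stimulation) cells before the
likelihood is evaluated: the per-trial Bernoulli log-likelihood
sum_i [y_i log p_i + (1-y_i) log(1-p_i)] depends on a cell only through its
trial count and PREF-choice count, so grouping changes nothing and makes each
evaluation O(#cells).  Multi-start optimization uses a seeded Latin-hypercube
over data-driven ranges, Nelder-Mead simplex search and a derivative-based
polish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

EPS_P = 1e-9  # probability clipping inside the likelihood
_PENALTY = 1e12  # likelihood value assigned to invalid parameter regions


@dataclass(frozen=True)
class CellData:
    """Grouped choice data: one entry per (C, alpha, beta) cell."""

    C: np.ndarray  # stimulus value per cell
    alpha: np.ndarray  # large-reward indicator
    beta: np.ndarray  # stimulation indicator
    n: np.ndarray  # trials per cell
    y: np.ndarray  # PREF choices per cell

    @property
    def n_trials(self) -> int:
        return int(self.n.sum())


def group_trials(
    trials: pd.DataFrame, stimulus_col: str = "C", alpha_col: str | None = "reward_category",
    beta_col: str = "microstim",
) -> CellData:
    """Collapse a trial table into choice-count cells.

    ``alpha_col=None`` treats all trials as a single reward condition
    (alpha = 0 throughout).
    """
    df = trials
    alpha = (
        (df[alpha_col] == "large").astype(int)
        if alpha_col is not None
        else pd.Series(0, index=df.index)
    )
    key = pd.DataFrame(
        {
            "C": df[stimulus_col].to_numpy(dtype=float),
            "alpha": alpha.to_numpy(),
            "beta": df[beta_col].to_numpy(dtype=int),
            "y": df["choice_pref"].to_numpy(dtype=int),
        }
    )
    g = key.groupby(["C", "alpha", "beta"], sort=True)["y"].agg(["size", "sum"]).reset_index()
    return CellData(
        C=g["C"].to_numpy(dtype=float),
        alpha=g["alpha"].to_numpy(dtype=float),
        beta=g["beta"].to_numpy(dtype=float),
        n=g["size"].to_numpy(dtype=float),
        y=g["sum"].to_numpy(dtype=float),
    )


def neg_log_likelihood(p: np.ndarray, cells: CellData) -> float:
    """Clipped Bernoulli negative log-likelihood of cell probabilities."""
    if not np.all(np.isfinite(p)):
        return _PENALTY
    p = np.clip(p, EPS_P, 1.0 - EPS_P)
    return float(-np.sum(cells.y * np.log(p) + (cells.n - cells.y) * np.log1p(-p)))


def penalty(violation: float) -> float:
    """Large finite objective for invalid parameter regions (keeps the simplex
    search well-behaved where +inf would stall it)."""
    return _PENALTY * (1.0 + abs(violation))


@dataclass
class MLEResult:
    theta: np.ndarray
    neg_log_likelihood: float
    converged: bool
    n_starts: int


def _latin_hypercube(lo: np.ndarray, hi: np.ndarray, n: int, seed) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    return lo + sampler.random(n) * (hi - lo)


def maximize(
    objective,
    start_lo: np.ndarray,
    start_hi: np.ndarray,
    n_starts: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
    extra_starts: list[np.ndarray] | None = None,
    tol: float = 1e-8,
) -> MLEResult:
    """Multi-start minimization of ``objective`` (a negative log-likelihood).

    Each start runs a Nelder-Mead simplex search followed by a BFGS polish;
    the best of all starts is returned.  ``extra_starts`` lets callers warm
    start nested/full model pairs from one another so likelihood dominance
    holds to optimizer tolerance.
    """
    lo = np.asarray(start_lo, dtype=float)
    hi = np.asarray(start_hi, dtype=float)
    starts = list(_latin_hypercube(lo, hi, n_starts, seed)) if n_starts > 0 else []
    for s in extra_starts or []:
        starts.append(np.asarray(s, dtype=float))
    if not starts:
        raise ValueError("need at least one start (n_starts > 0 or extra_starts)")

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": 400 * len(x0)},
        )
        polish = optimize.minimize(objective, res.x, method="BFGS", options={"gtol": 1e-7})
        cand = polish if polish.fun <= res.fun else res
        if cand.fun < _PENALTY / 2:
            any_converged = any_converged or bool(cand.success or res.success)
        if best is None or cand.fun < best.fun:
            best = cand
    assert best is not None
    return MLEResult(
        theta=np.asarray(best.x, dtype=float),
        neg_log_likelihood=float(best.fun),
        converged=any_converged and best.fun < _PENALTY / 2,
        n_starts=len(starts),
    )
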