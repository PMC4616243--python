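"""Fixed-viewing-duration bounded drift-diffusion simulator.

One decision variable (DV) accumulates momentary evidence e = k*C (plus an
electrically injected increment m on stimulated trials) with unit diffusion
noise, between symmetric absorbing bounds at +/-B, for a fixed viewing
duration T.  The choice is the first bound crossed; if neither is crossed it
is the sign of the DV at stimulus offset (a DV of exactly zero is resolved by
a fair coin).  Only k/noise and B/noise are identifiable, so the diffusion
coefficient is fixed at 1 per sqrt(second) -- the standard DDM scaling
convention.  There are no reaction-time outputs: the task is fixed-duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import expit


@dataclass(frozen=True)
class DDMConfig:
    k: float = 2.0  # drift per unit normalized disparity per second
    bound: float = 1.0  # symmetric absorbing bounds at +/- bound (DV units)
    stim_evidence: float = 1.0  # drift increment m on microstimulated trials
    start: float = 0.0  # DV at t = 0
    noise_sd: float = 1.0  # diffusion coefficient per sqrt(second)
    dt: float = 1e-3  # Euler-Maruyama step, seconds
    T: float = 2.0  # viewing duration, seconds
    n_paths: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise ValueError("bound must be > 0")
        if not (0 < self.dt <= self.T):
            raise ValueError("dt must lie in (0, T]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def choice_probability(cfg: DDMConfig, C: float, microstim: bool = False) -> tuple[float, float]:
    """Monte-Carlo estimate of P(PREF choice) and its binomial standard error.

    Euler-Maruyama paths with drift k*C (+ stim_evidence when microstimulated)
    absorbed at +/-bound; undecided paths choose the nearer bound (the sign of
    the final DV), with a fair coin at exactly zero.
    """
    if cfg.n_paths <= 0:
        raise ValueError("n_paths must be > 0")
    rng = np.random.default_rng(cfg.seed)
    drift = cfg.k * C + (cfg.stim_evidence if microstim else 0.0)
    n_steps = int(round(cfg.T / cfg.dt))
    sqdt = np.sqrt(cfg.dt)

    dv = np.full(cfg.n_paths, cfg.start, dtype=float)
    decided = np.zeros(cfg.n_paths, dtype=bool)
    choice = np.zeros(cfg.n_paths, dtype=bool)
    for _ in range(n_steps):
        active = ~decided
        if not active.any():
            break
        dv[active] += drift * cfg.dt + cfg.noise_sd * sqdt * rng.standard_normal(active.sum())
        hit_up = active & (dv >= cfg.bound)
        hit_dn = active & (dv <= -cfg.bound)
        choice[hit_up] = True
        decided |= hit_up | hit_dn
    undecided = ~decided
    if undecided.any():
        final = dv[undecided]
        pick = final > 0
        ties = final == 0
        if ties.any():
            pick = pick | (ties & (rng.random(ties.size) < 0.5))
        choice[undecided] = pick
    p = float(choice.mean())
    se = float(np.sqrt(max(p * (1 - p), 1.0 / cfg.n_paths)) / np.sqrt(cfg.n_paths))
    return p, se


def analytic_pse(cfg: DDMConfig, microstim: bool = True) -> float:
    """Disparity of zero net drift, where P(PREF) = 0.5 for an unbiased start.

    Stimulated: -m/k; non-stimulated: 0.  The stimulated-vs-non-stimulated PSE
    shift is therefore m/k, independent of the bound.
    """
    if cfg.start != 0:
        raise ValueError("analytic PSE assumes an unbiased starting point")
    if cfg.k == 0:
        raise ValueError("k = 0: PSE undefined")
    return -cfg.stim_evidence / cfg.k if microstim else 0.0


def psychometric_curve(
    cfg: DDMConfig, grid: np.ndarray, microstim: bool = False
) -> np.ndarray:
    """Monte-Carlo psychometric function over a disparity grid.

    Returns an array of rows (C, p_hat, se); each grid point uses an
    independent substream of the config seed.
    """
    rows = []
    ss = np.random.SeedSequence([int(cfg.seed), int(microstim)])
    children = ss.spawn(len(grid))
    for Ci, child in zip(np.asarray(grid, dtype=float), children):
        sub = replace(cfg, seed=child.generate_state(1)[0] % (2**31))
        p, se = choice_probability(sub, Ci, microstim)
        rows.append((Ci, p, se))
    return np.array(rows)


def fit_logistic_curve(C: np.ndarray, p_hat: np.ndarray, n: int) -> tuple[float, float]:
    """Fit p = logistic(gain * (C - pse)) to Monte-Carlo curve estimates by
    binomial maximum likelihood; returns (gain, pse)."""
    C = np.asarray(C, dtype=float)
    y = np.asarray(p_hat, dtype=float) * n

    def nll(theta):
        gain, pse = theta
        p = np.clip(expit(gain * (C - pse)), 1e-9, 1 - 1e-9)
        return -np.sum(y * np.log(p) + (n - y) * np.log1p(-p))

    best = None
    for g0 in (0.5, 2.0, 8.0):
        res = optimize.minimize(nll, np.array([g0, 0.0]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])
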