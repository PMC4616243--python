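"""Synthetic-session generator emulating the task, reward schedule and
stimulation design that the analysis assumes.

Each session draws disparities pseudo-randomly from a symmetric normalized
grid that includes the ambiguous zero level, interleaves stimulation on a
random half of trials, tracks the consecutive-correct streak to set the
available reward (and hence the large/small category) *before* the choice,
and draws the choice from the bounded-accumulation model (or from Monte-Carlo
drift-diffusion probabilities).  Zero-disparity trials are paid by a fair
coin and do not advance the streak.  In delta-dx mode the flagged trials get
a small extra disparity added to the displayed stimulus (not to the reward
computation) in place of the electrical evidence term, mimicking the overtly
cued visual-perturbation control.

Default truth parameters are of the magnitude estimated from pooled monkey
data (k0 ~ 1.9, k1 ~ 1.6, B0 ~ 1.3, B1 ~ -0.5 on normalized disparity), with
~500 trials per site and a 7-level grid, the scale of a typical
microstimulation session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accumulation import accumulation_probability
from .ddm import DDMConfig, choice_probability
from .reward import RewardSchedule, get_schedule, reward_for_streak
from .trial_data import SiteMeta, TRIAL_COLUMNS, site_meta_to_row

DEFAULT_LEVELS = (-1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0)

DEFAULT_TRUTH = {
    "k0": 1.94, "k1": 1.56, "k2": 0.3,
    "B0": 1.29, "B1": -0.50,
    "x0": 0.1, "x1": 0.0,
}


@dataclass
class GeneratorConfig:
    n_trials: int = 500
    disparity_levels: tuple[float, ...] = DEFAULT_LEVELS  # normalized, includes 0
    microstim_fraction: float = 0.5
    params: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    schedule: RewardSchedule | None = None  # defaults to the animal's built-in
    mode: str = "logistic"  # or "ddm"
    delta_dx_mode: bool = False
    delta_dx_disparity_deg: float = 0.005
    max_abs_disparity_deg: float = 0.04
    site_id: str = "syn000"
    animal_id: str = "ica"
    seed: int = 0
    ddm_n_paths: int = 4000  # Monte-Carlo paths per cell in ddm mode
    ddm_stim_evidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.microstim_fraction < 1):
            raise ValueError("microstim_fraction must lie in (0, 1)")
        if any(abs(c) > 1 for c in self.disparity_levels):
            raise ValueError("normalized disparity levels must lie in [-1, 1]")
        if self.mode not in ("logistic", "ddm"):
            raise ValueError("mode must be 'logistic' or 'ddm'")
        if self.schedule is None:
            self.schedule = get_schedule(self.animal_id)


def _ddm_cell_probabilities(cfg: GeneratorConfig) -> dict[tuple[float, int, int], float]:
    """Monte-Carlo choice probability per (C, alpha, beta) cell.

    The accumulation parameters map onto the diffusion as: drift sensitivity
    k_eff = k0 + a*k1 + b*k2, bound B_eff = B0 + a*B1, electrical drift
    increment ``ddm_stim_evidence`` on stimulated trials, and the null bias
    x_eff applied as a starting-point offset in DV units.
    """
    p = cfg.params
    out: dict[tuple[float, int, int], float] = {}
    ss = np.random.SeedSequence([int(cfg.seed), 7_919])
    combos = [(C, a, b) for C in cfg.disparity_levels for a in (0, 1) for b in (0, 1)]
    for (C, a, b), child in zip(combos, ss.spawn(len(combos))):
        k_eff = p["k0"] + a * p["k1"] + b * p["k2"]
        B_eff = p["B0"] + a * p["B1"]
        x_eff = p["x0"] + a * p["x1"]
        ddm = DDMConfig(
            k=k_eff,
            bound=B_eff,
            stim_evidence=cfg.ddm_stim_evidence if b else 0.0,
            start=float(np.clip(x_eff, -0.9 * B_eff, 0.9 * B_eff)),
            n_paths=cfg.ddm_n_paths,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        out[(C, a, b)], _ = choice_probability(ddm, C, microstim=bool(b))
    return out


def simulate_session(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate one session's trial table (canonical column order)."""
    n = cfg.n_trials
    if n == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    rng = np.random.default_rng(cfg.seed)
    levels = np.asarray(cfg.disparity_levels, dtype=float)
    idx = rng.integers(0, len(levels), size=n)
    flagged = rng.random(n) < cfg.microstim_fraction
    u_choice = rng.random(n)
    u_coin = rng.random(n)

    ddm_p = _ddm_cell_probabilities(cfg) if cfg.mode == "ddm" else None
    delta_norm = cfg.delta_dx_disparity_deg / cfg.max_abs_disparity_deg
    p_par = cfg.params

    rows = {c: [] for c in TRIAL_COLUMNS}
    streak = 0
    for i in range(n):
        C = float(levels[idx[i]])
        flag = bool(flagged[i])
        volume, category = reward_for_streak(cfg.schedule, streak)
        alpha = 1 if category == "large" else 0
        if cfg.delta_dx_mode:
            # Visual perturbation: extra disparity on the display, no
            # electrical term, reward computed from the base disparity.
            C_display = C + delta_norm if flag else C
            p = float(accumulation_probability(p_par, C_display, alpha, 0))
            microstim, delta_dx = 0, int(flag)
        else:
            beta = int(flag)
            if ddm_p is not None:
                p = ddm_p[(C, alpha, beta)]
            else:
                p = float(accumulation_probability(p_par, C, alpha, beta))
            microstim, delta_dx = beta, 0
        choice = int(u_choice[i] < p)
        if C != 0.0:
            correct = int(choice == int(C > 0))
            rewarded = correct
            streak = streak + 1 if correct else 0
        else:
            correct = None
            rewarded = int(u_coin[i] < 0.5)
        rows["site_id"].append(cfg.site_id)
        rows["animal_id"].append(cfg.animal_id)
        rows["trial_index"].append(i)
        rows["disparity_deg"].append(C * cfg.max_abs_disparity_deg)
        rows["microstim"].append(microstim)
        rows["available_reward_ml"].append(volume)
        rows["reward_category"].append(category)
        rows["choice_pref"].append(choice)
        rows["correct"].append(correct)
        rows["rewarded"].append(rewarded)
        rows["delta_dx"].append(delta_dx)
    df = pd.DataFrame(rows)
    df["correct"] = pd.array(rows["correct"], dtype="Int64")
    return df


def simulate_from_gaussian(
    params: dict,
    n_trials: int,
    disparity_levels: tuple[float, ...] = DEFAULT_LEVELS,
    microstim_fraction: float = 0.5,
    large_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw choices directly from the pooled cumulative-Gaussian model.

    A vectorized model-based generator for calibration and power studies of
    the Gaussian family: reward and stimulation flags are i.i.d. coins rather
    than streak-driven, and disparity is already normalized.  ``params`` maps
    mu0..mu3, sigma0..sigma2 (missing entries default to 0).
    """
    from scipy.special import ndtr as _ndtr

    rng = np.random.default_rng(seed)
    levels = np.asarray(disparity_levels, dtype=float)
    C = levels[rng.integers(0, len(levels), size=n_trials)]
    beta = (rng.random(n_trials) < microstim_fraction).astype(int)
    alpha = (rng.random(n_trials) < large_fraction).astype(int)
    g = dict.fromkeys(("mu0", "mu1", "mu2", "mu3", "sigma0", "sigma1", "sigma2"), 0.0)
    g.update(params)
    mean = g["mu0"] + beta * g["mu1"] + alpha * g["mu2"] + alpha * beta * g["mu3"]
    sd = g["sigma0"] + alpha * g["sigma1"] + beta * g["sigma2"]
    if np.any(sd <= 0):
        raise ValueError("effective sigma must be > 0 for every cell")
    p = _ndtr((C - mean) / sd)
    choice = (rng.random(n_trials) < p).astype(int)
    return pd.DataFrame(
        {
            "C": C,
            "microstim": beta,
            "reward_category": np.where(alpha == 1, "large", "small"),
            "choice_pref": choice,
        }
    )


def simulate_site_set(
    n_sites: int,
    eccentricity_range: tuple[float, float] = (2.0, 14.0),
    base_params: dict | None = None,
    n_trials_per_site: int = 500,
    disparity_levels: tuple[float, ...] = DEFAULT_LEVELS,
    animals: tuple[str, ...] = ("fle", "ica"),
    threshold_intercept_deg: float = 0.005,
    threshold_slope_deg_per_deg: float = 0.004,
    sensitivity_jitter_sd: float = 0.15,
    mode: str = "logistic",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a multi-site dataset with eccentricity-dependent thresholds.

    Each site's receptive-field eccentricity is drawn uniformly over the
    range; the site's maximum (threshold-matched) disparity grows linearly
    with eccentricity, so raw thresholds worsen with eccentricity while the
    normalized task difficulty stays constant.  Per-site sensitivity and gain
    receive small lognormal jitter.  Returns (trials, sites, per-site truth);
    the same seed gives bit-identical output.
    """
    base = dict(DEFAULT_TRUTH if base_params is None else base_params)
    trials_frames, site_rows, truth_rows = [], [], []
    master = np.random.SeedSequence(seed)
    children = master.spawn(max(n_sites, 1))
    for i in range(n_sites):
        child = children[i]
        site_rng = np.random.default_rng(child)
        ecc = float(site_rng.uniform(*eccentricity_range))
        max_abs = threshold_intercept_deg + threshold_slope_deg_per_deg * ecc
        animal = animals[i % len(animals)]
        params = dict(base)
        jitter = site_rng.lognormal(0.0, sensitivity_jitter_sd, size=2)
        params["k0"] = base["k0"] * float(jitter[0])
        params["B0"] = base["B0"] * float(jitter[1])
        pref = "CW" if site_rng.random() < 0.5 else "CCW"
        site_id = f"{animal}{300 + i:03d}"
        cfg = GeneratorConfig(
            n_trials=n_trials_per_site,
            disparity_levels=disparity_levels,
            params=params,
            mode=mode,
            max_abs_disparity_deg=max_abs,
            site_id=site_id,
            animal_id=animal,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        trials_frames.append(simulate_session(cfg))
        meta = SiteMeta(
            site_id=site_id,
            animal_id=animal,
            pref_direction=pref,
            eccentricity_deg=ecc,
            max_abs_disparity_deg=max_abs,
            disparity_levels=tuple(np.round(np.asarray(disparity_levels) * max_abs, 12)),
        )
        site_rows.append(site_meta_to_row(meta))
        truth_rows.append({"site_id": site_id, **params})
    trials = (
        pd.concat(trials_frames, ignore_index=True)
        if trials_frames
        else pd.DataFrame(columns=TRIAL_COLUMNS)
    )
    sites = pd.DataFrame(site_rows, columns=["site_id", "animal_id", "pref_direction",
                                             "eccentricity_deg", "max_abs_disparity_deg",
                                             "disparity_levels"])
    truth = pd.DataFrame(truth_rows)
    return trials, sites, truth
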