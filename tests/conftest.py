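"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rewardstim.simulate import GeneratorConfig, simulate_session

SEED = 12345  # global test seed, fixed for the whole suite


def make_trials(
    disparity_deg,
    microstim,
    choice_pref,
    reward_category=None,
    site_id="s1",
    animal_id="ica",
    delta_dx=None,
    available_reward_ml=None,
) -> pd.DataFrame:
    """Hand-build a canonical trial table from per-trial arrays; correctness,
    payout and defaults are filled in from the task rules."""
    n = len(disparity_deg)
    d = np.asarray(disparity_deg, dtype=float)
    choice = np.asarray(choice_pref, dtype=int)
    correct = [None if di == 0 else int(ci == int(di > 0)) for di, ci in zip(d, choice)]
    rewarded = [c if c is not None else 0 for c in correct]
    cat = list(reward_category) if reward_category is not None else ["small"] * n
    vol = (
        np.asarray(available_reward_ml, dtype=float)
        if available_reward_ml is not None
        else np.where(np.asarray(cat) == "large", 0.2, 0.08)
    )
    df = pd.DataFrame(
        {
            "site_id": site_id,
            "animal_id": animal_id,
            "trial_index": np.arange(n),
            "disparity_deg": d,
            "microstim": np.asarray(microstim, dtype=int),
            "available_reward_ml": vol,
            "reward_category": cat,
            "choice_pref": choice,
            "correct": pd.array(correct, dtype="Int64"),
            "rewarded": rewarded,
            "delta_dx": np.zeros(n, dtype=int) if delta_dx is None else np.asarray(delta_dx, int),
        }
    )
    return df


@pytest.fixture(scope="session")
def session_10k() -> pd.DataFrame:
    """One 10k-trial synthetic session at the default truth, with normalized
    disparity attached; shared across read-only tests."""
    cfg = GeneratorConfig(n_trials=10_000, seed=SEED)
    df = simulate_session(cfg)
    df["C"] = df["disparity_deg"] / cfg.max_abs_disparity_deg
    return df


@pytest.fixture(scope="session")
def session_cfg() -> GeneratorConfig:
    return GeneratorConfig(n_trials=10_000, seed=SEED)
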