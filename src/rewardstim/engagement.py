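"""Task-engagement time-series controls: sliding-window performance
smoothing, fluctuation quantification, good/bad epoch segmentation,
epoch-wise reward-by-stimulation tests, and the waning-of-stimulation
control.

Smoothing is a trailing (causal) 30-trial window over trials with a defined
correct answer; ambiguous zero-disparity trials are excluded from the
accuracy computation but inherit the epoch label of their position in the
session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaussian import LRResult, pooled_reward_interaction
from .population import correlation

DEFAULT_WINDOW = 30


@dataclass
class Epoch:
    start: int  # trial_index of the first smoothed point in the run
    end: int  # trial_index of the last smoothed point in the run
    label: str  # "good" | "bad"
    length: int  # number of smoothed points in the run


@dataclass
class EngagementProfile:
    window: int
    smoothed_accuracy: pd.Series  # indexed by trial_index (defined trials only)
    session_mean: float
    fluctuation_area_norm: float
    epochs: list[Epoch]
    n_trials: int


def smoothed_accuracy(trials: pd.DataFrame, window: int = DEFAULT_WINDOW) -> pd.Series:
    """Trailing-window proportion correct, aligned to the window's last trial.

    Computed over trials with a defined correct answer, ordered by
    trial_index; the series starts once a full window is available.
    """
    defined = trials[trials["correct"].notna()].sort_values("trial_index")
    if len(defined) < window:
        raise ValueError(f"need at least {window} trials with a defined outcome, got {len(defined)}")
    correct = defined["correct"].astype(float)
    series = correct.rolling(window).mean().dropna()
    series.index = defined["trial_index"].to_numpy()[window - 1 :]
    series.name = "smoothed_accuracy"
    return series


def fluctuation_area(series: pd.Series, session_mean: float, n_trials: int) -> float:
    """Trapezoidal area between the smoothed curve and the session mean,
    normalized by the total number of trials in the session."""
    dev = np.abs(series.to_numpy(dtype=float) - session_mean)
    if dev.size < 2:
        return 0.0
    return float(np.trapezoid(dev, x=series.index.to_numpy(dtype=float)) / n_trials)


def segment_epochs(series: pd.Series, session_mean: float, window: int = DEFAULT_WINDOW) -> list[Epoch]:
    """Maximal runs strictly above ('good') or strictly below ('bad') the
    session mean lasting at least ``window`` smoothed points; points exactly
    at the mean break runs and stay unlabeled."""
    values = series.to_numpy(dtype=float)
    index = series.index.to_numpy()
    state = np.where(values > session_mean, 1, np.where(values < session_mean, -1, 0))
    epochs: list[Epoch] = []
    i = 0
    while i < len(state):
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(state) and state[j + 1] == state[i]:
            j += 1
        length = j - i + 1
        if length >= window:
            epochs.append(
                Epoch(
                    start=int(index[i]),
                    end=int(index[j]),
                    label="good" if state[i] == 1 else "bad",
                    length=length,
                )
            )
        i = j + 1
    return epochs


def compute_profile(trials: pd.DataFrame, window: int = DEFAULT_WINDOW) -> EngagementProfile:
    """Full engagement profile for one session."""
    series = smoothed_accuracy(trials, window)
    defined = trials["correct"].dropna().astype(float)
    session_mean = float(defined.mean())
    area = fluctuation_area(series, session_mean, len(trials))
    epochs = segment_epochs(series, session_mean, window)
    return EngagementProfile(
        window=window,
        smoothed_accuracy=series,
        session_mean=session_mean,
        fluctuation_area_norm=area,
        epochs=epochs,
        n_trials=len(trials),
    )


def label_trials(trials: pd.DataFrame, profile: EngagementProfile) -> pd.Series:
    """Epoch label per trial of one session ('' when unlabeled); a trial gets
    the label of the epoch whose [start, end] trial_index range contains it."""
    labels = pd.Series("", index=trials.index, dtype=object)
    ti = trials["trial_index"].to_numpy()
    for epoch in profile.epochs:
        labels[(ti >= epoch.start) & (ti <= epoch.end)] = epoch.label
    return labels


def epoch_pooled_test(
    labeled_trials: pd.DataFrame, n_starts: int = 10, seed: int = 0
) -> dict[str, LRResult]:
    """Within each epoch label, test the reward-by-stimulation interaction
    (full pooled Gaussian vs mu3 frozen) on the pooled, normalized trials.

    ``labeled_trials`` must carry columns ``C`` and ``epoch_label``.  Labels
    missing a reward or stimulation condition are skipped with a warning.
    """
    out: dict[str, LRResult] = {}
    for label in ("good", "bad"):
        sub = labeled_trials[labeled_trials["epoch_label"] == label]
        if len(sub) == 0:
            warnings.warn(f"no trials in {label!r} epochs; skipped", stacklevel=2)
            continue
        if sub["reward_category"].nunique() < 2 or sub["microstim"].nunique() < 2:
            warnings.warn(f"{label!r} epochs lack a reward or stimulation condition; skipped",
                          stacklevel=2)
            continue
        res = pooled_reward_interaction(sub, n_starts=n_starts, seed=seed)
        out[label] = res["reward_on_shift"]
    return out


def large_reward_trend(trials: pd.DataFrame) -> float:
    """Slope (per trial) of the best-fit line through the expanding running
    proportion of large-reward trials over one session."""
    sub = trials.sort_values("trial_index")
    indicator = (sub["reward_category"] == "large").astype(float).to_numpy()
    running = np.cumsum(indicator) / np.arange(1, len(indicator) + 1)
    t = sub["trial_index"].to_numpy(dtype=float)
    if np.allclose(running, running[0]):
        return 0.0
    slope, _ = np.polyfit(t, running, 1)
    return float(slope)


def waning_control(trials: pd.DataFrame, site_effects: pd.DataFrame) -> dict:
    """Does a drift toward large-reward trials late in the session explain the
    reward effect?  Per site: OLS slope of the running large-reward
    proportion; across sites: Spearman and Pearson correlations of the
    normalized reward effect against that slope."""
    slopes = {
        str(site_id): large_reward_trend(sub) for site_id, sub in trials.groupby("site_id")
    }
    df = site_effects.copy()
    df["large_reward_slope"] = df["site_id"].map(slopes)
    df = df.dropna(subset=["large_reward_slope", "reward_effect_norm"])
    if len(df) < 3:
        raise ValueError("need at least 3 sites for the waning control")
    out = {"per_site_slopes": slopes}
    for method in ("spearman", "pearson"):
        r, p = correlation(df["reward_effect_norm"], df["large_reward_slope"], method=method)
        out[method] = {"r": r, "p": p, "n": int(len(df))}
    return out
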