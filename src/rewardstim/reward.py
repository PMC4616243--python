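"""Performance-contingent reward schedules and the consecutive-correct streak state.

The task pays a fluid reward for each correct two-alternative choice, with the
available volume escalating in two steps over consecutive correct responses up
to a schedule maximum.  Trials at the maximum are the "large"-reward condition;
everything sub-maximal is "small".  Ambiguous (zero-disparity) trials are paid
by a fair coin and are discounted when counting the streak.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RewardSchedule:
    """Mapping from streak position (1-based) to reward volume in ml.

    ``volumes_by_streak[n-1]`` is the volume paid for the n-th consecutive
    correct choice; the last entry repeats for all longer streaks.  Volumes
    must be non-decreasing.  The reward *category* is ``"large"`` exactly when
    the volume equals the schedule maximum.
    """

    animal_id: str
    volumes_by_streak: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.volumes_by_streak:
            raise ValueError("schedule needs at least one volume")
        vols = self.volumes_by_streak
        if any(b < a for a, b in zip(vols, vols[1:])):
            raise ValueError("reward volumes must be non-decreasing in streak position")
        if any(v < 0 for v in vols):
            raise ValueError("reward volumes must be >= 0")

    @property
    def max_volume(self) -> float:
        return self.volumes_by_streak[-1]

    def volume_at(self, streak_position: int) -> float:
        """Volume for the given 1-based streak position."""
        if streak_position < 1:
            raise ValueError("streak position is 1-based")
        idx = min(streak_position, len(self.volumes_by_streak)) - 1
        return self.volumes_by_streak[idx]


def ica_schedule() -> RewardSchedule:
    """Slow-escalation schedule ('ica'): 0.08 ml on the 1st/2nd consecutive
    correct, 0.12 ml on the 3rd, 0.20 ml from the 4th onward."""
    return RewardSchedule("ica", (0.08, 0.08, 0.12, 0.20))


def fle_schedule(max_volume: float = 0.18) -> RewardSchedule:
    """Fast-escalation schedule ('fle'): 1/3 of maximum on the 1st correct,
    2/3 on the 2nd, maximum (default 0.18 ml) from the 3rd onward."""
    return RewardSchedule("fle", (max_volume / 3.0, 2.0 * max_volume / 3.0, max_volume))


BUILTIN_SCHEDULES = {"ica": ica_schedule, "fle": fle_schedule}


def get_schedule(animal_id: str) -> RewardSchedule:
    try:
        return BUILTIN_SCHEDULES[animal_id.lower()]()
    except KeyError:
        raise KeyError(f"no built-in schedule for animal {animal_id!r}") from None


def reward_for_streak(schedule: RewardSchedule, preceding_correct: int) -> tuple[float, str]:
    """Available reward (volume, category) given the number of immediately
    preceding consecutive correct responses.

    The current trial, if correct, would be streak position
    ``preceding_correct + 1``; that position's volume is what is at stake.
    """
    if preceding_correct < 0:
        raise ValueError("preceding_correct must be >= 0")
    volume = schedule.volume_at(preceding_correct + 1)
    category = "large" if volume == schedule.max_volume else "small"
    return volume, category


@dataclass
class StreakState:
    """Count of immediately preceding consecutive correct responses."""

    consecutive_correct: int = 0


def update_streak(state: StreakState, correct: bool | None, disparity: float) -> StreakState:
    """Advance the streak after a trial.

    Zero-disparity trials have no defined correct answer and are discounted:
    the streak passes through unchanged.  Otherwise a correct response
    increments the count and an error resets it to zero.
    """
    if disparity == 0:
        if correct is not None:
            raise ValueError("zero-disparity trials have undefined correctness")
        return StreakState(state.consecutive_correct)
    if correct is None:
        raise ValueError("non-zero-disparity trials must have a defined outcome")
    return StreakState(state.consecutive_correct + 1 if correct else 0)
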