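"""One-up/one-down adaptive staircase with a 2AFC response protocol.

Each trial presents the test tone in one of two observation intervals chosen
uniformly at random; the responder (a virtual listener or an interactive
callback) picks an interval. A correct identification lowers the level, a
wrong one raises it, with step sizes that shrink as reversal points
accumulate. The run ends after a fixed number of reversals and the threshold
is the mean level over the last few reversals; runs whose final reversal
levels scatter too widely are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol

import numpy as np


class Responder(Protocol):
    """Maps a presentation to the chosen interval (1 or 2)."""

    def __call__(
        self, level: float, signal_interval: int, rng: np.random.Generator
    ) -> int: ...


def step_schedule_default(
    initial_increment: float = 12.0,
    initial_decrement: float = 4.0,
    final_increment: float = 3.0,
    final_decrement: float = 1.0,
    floor_index: int = 4,
) -> Callable[[int], tuple[float, float]]:
    """Step sizes as a function of the number of reversals so far.

    Both step sizes halve after each early reversal (12→6→3 dB up, 4→2→1 dB
    down by default) and are clamped to their final values from
    ``floor_index`` reversals onward at the latest.
    """

    def schedule(reversal_index: int) -> tuple[float, float]:
        if reversal_index >= floor_index:
            return final_increment, final_decrement
        inc = max(initial_increment / 2**reversal_index, final_increment)
        dec = max(initial_decrement / 2**reversal_index, final_decrement)
        return inc, dec

    return schedule


@dataclass
class StaircaseConfig:
    """Parameters of the adaptive threshold run.

    The defaults implement the standard schedule: 12-reversal runs, threshold
    from the last 8 reversal levels, rejection when those 8 span more than
    15 dB, and a 4-dB start-level bump available until the first reversal.
    """

    start_level: float = 70.0
    initial_increment: float = 12.0
    initial_decrement: float = 4.0
    final_increment: float = 3.0
    final_decrement: float = 1.0
    n_reversals_total: int = 12
    n_reversals_averaged: int = 8
    rejection_span: float = 15.0
    pre_reversal_bump: float = 4.0
    max_trials: int = 200
    step_schedule: Callable[[int], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.final_increment > self.initial_increment:
            raise ValueError("final_increment must not exceed initial_increment")
        if self.final_decrement > self.initial_decrement:
            raise ValueError("final_decrement must not exceed initial_decrement")
        if self.n_reversals_averaged > self.n_reversals_total:
            raise ValueError("cannot average more reversals than are collected")
        if self.step_schedule is None:
            self.step_schedule = step_schedule_default(
                self.initial_increment,
                self.initial_decrement,
                self.final_increment,
                self.final_decrement,
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "StaircaseConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown staircase config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass(frozen=True)
class TrialRecord:
    index: int
    level: float
    signal_interval: int
    chosen_interval: int
    correct: bool
    is_reversal: bool

    def __post_init__(self) -> None:
        if self.correct != (self.chosen_interval == self.signal_interval):
            raise ValueError("correct flag inconsistent with intervals")


@dataclass
class StaircaseResult:
    trials: list[TrialRecord]
    reversal_levels: list[float]
    threshold: float | None
    rejected: bool
    incomplete: bool
    bump_count: int


class Staircase:
    """Stateful staircase; drive it trial by trial or via :func:`run_staircase`.

    The start-level bump (used by participants to signal an inaudible start
    level) is only available before the first reversal.
    """

    def __init__(self, config: StaircaseConfig, rng_seed: int):
        self.config = config
        self.rng = np.random.default_rng(rng_seed)
        self.level = float(config.start_level)
        self.trials: list[TrialRecord] = []
        self.reversal_levels: list[float] = []
        self.bump_count = 0
        self._prev_correct: bool | None = None

    @property
    def done(self) -> bool:
        return (
            len(self.reversal_levels) >= self.config.n_reversals_total
            or len(self.trials) >= self.config.max_trials
        )

    def apply_pre_reversal_bump(self) -> None:
        """Raise the current level by the configured bump amount.

        Refused once the first reversal point has been reached.
        """
        if self.reversal_levels:
            raise RuntimeError("start-level bump not available after the first reversal")
        self.level += self.config.pre_reversal_bump
        self.bump_count += 1

    def run_trial(self, responder: Responder) -> TrialRecord:
        signal_interval = int(self.rng.integers(1, 3))
        chosen = responder(self.level, signal_interval, self.rng)
        if chosen not in (1, 2):
            raise ValueError("responder must choose interval 1 or 2")
        correct = chosen == signal_interval
        is_reversal = self._prev_correct is not None and correct != self._prev_correct
        trial = TrialRecord(
            index=len(self.trials),
            level=self.level,
            signal_interval=signal_interval,
            chosen_interval=chosen,
            correct=correct,
            is_reversal=is_reversal,
        )
        self.trials.append(trial)
        if is_reversal:
            self.reversal_levels.append(self.level)
        inc, dec = self.config.step_schedule(len(self.reversal_levels))
        self.level = self.level - dec if correct else self.level + inc
        self._prev_correct = correct
        return trial

    def result(self) -> StaircaseResult:
        cfg = self.config
        incomplete = len(self.reversal_levels) < cfg.n_reversals_total
        threshold = None
        rejected = False
        if not incomplete:
            last = self.reversal_levels[-cfg.n_reversals_averaged :]
            rejected = (max(last) - min(last)) > cfg.rejection_span
            if not rejected:
                threshold = float(np.mean(last))
        return StaircaseResult(
            trials=list(self.trials),
            reversal_levels=list(self.reversal_levels),
            threshold=threshold,
            rejected=rejected,
            incomplete=incomplete,
            bump_count=self.bump_count,
        )


def run_staircase(
    responder: Responder, config: StaircaseConfig, rng_seed: int
) -> StaircaseResult:
    """Run a complete staircase against ``responder``.

    Terminates after ``n_reversals_total`` reversals, or is flagged
    ``incomplete`` when ``max_trials`` is hit first (distinct from
    ``rejected``, which marks inconsistent responses at full length).
    """
    sc = Staircase(config, rng_seed)
    while not sc.done:
        sc.run_trial(responder)
    return sc.result()
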