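"""Adaptive 2-down/1-up staircase for ripple-velocity discrimination.

The staircase tracks the just-noticeable difference (JND) of base-2
logarithmic ripple-velocity intervals: the tested interval Delta (in log2
units of cycles/s) shrinks after two consecutive correct responses and grows
after each incorrect one.  A 2-down/1-up rule converges on the ~70.7 %
correct point of the observer's psychometric function.

The observer is any callable ``P(delta) -> probability correct`` with range
[0.5, 1] (chance for a 2-alternative task is 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = ["StaircaseConfig", "StaircaseResult", "simulate_staircase"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Staircase rule and schedule.

    Step sizes are in log2 units of ripple velocity and must be positive and
    non-increasing; after the list is exhausted the last step size is kept.
    By default the step halves after each of the first two reversals, the
    staircase stops after 8 reversals, and the JND estimate averages the
    Delta values at the last 6 reversals.
    """

    n_down: int = 2
    n_up: int = 1
    initial_interval: float = 2.0
    step_sizes: Sequence[float] = (0.4, 0.2, 0.1)
    n_reversals: int = 8
    estimate_reversals: int = 6
    min_interval: float = 0.05
    max_interval: float = 4.0  # log2(48/3): the velocity range is 3-48 cycles/s
    max_trials: int = 400

    def validate(self) -> None:
        steps = np.asarray(self.step_sizes, dtype=float)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValueError("step sizes must be positive")
        if np.any(np.diff(steps) > 0):
            raise ValueError("step sizes must be non-increasing")
        if not (0 < self.min_interval < self.max_interval):
            raise ValueError("interval bounds must satisfy 0 < min < max")
        if self.estimate_reversals > self.n_reversals:
            raise ValueError("cannot average more reversals than are collected")
        if self.n_down < 1 or self.n_up < 1:
            raise ValueError("n_down and n_up must be >= 1")


@dataclass
class StaircaseResult:
    estimate: float
    trace: pd.DataFrame  # columns: trial, delta, correct, reversal
    reversal_deltas: list = field(default_factory=list)
    hit_upper_bound: bool = False  # > 50% of trials pinned at the upper bound


def simulate_staircase(
    config: StaircaseConfig,
    observer: Callable[[float], float],
    seed: int = 0,
) -> StaircaseResult:
    """Run one simulated staircase against a stochastic observer.

    The estimate is the mean Delta at the last ``estimate_reversals``
    reversals.  If the track sits at the upper interval bound for more than
    half of its trials the result is flagged (``hit_upper_bound``): the
    observer was effectively at chance and the estimate is not meaningful.
    """
    config.validate()
    rng = child_rng(seed, "staircase")

    delta = float(np.clip(config.initial_interval, config.min_interval, config.max_interval))
    steps = list(config.step_sizes)
    step_idx = 0
    n_correct_run = 0
    n_wrong_run = 0
    direction = 0  # -1 moving down, +1 moving up
    reversal_deltas: list[float] = []
    rows = []
    n_at_upper = 0

    for trial in range(config.max_trials):
        p = float(observer(delta))
        p = min(max(p, 0.0), 1.0)
        correct = bool(rng.random() < p)
        if delta >= config.max_interval:
            n_at_upper += 1

        move = 0
        if correct:
            n_correct_run += 1
            n_wrong_run = 0
            if n_correct_run >= config.n_down:
                move = -1
                n_correct_run = 0
        else:
            n_wrong_run += 1
            n_correct_run = 0
            if n_wrong_run >= config.n_up:
                move = +1
                n_wrong_run = 0

        reversal = move != 0 and direction != 0 and move != direction
        rows.append((trial, delta, correct, reversal))
        if reversal:
            reversal_deltas.append(delta)
            if step_idx < len(steps) - 1:
                step_idx += 1
            if len(reversal_deltas) >= config.n_reversals:
                break
        if move != 0:
            direction = move
            delta = float(
                np.clip(delta + move * steps[step_idx], config.min_interval, config.max_interval)
            )

    trace = pd.DataFrame(rows, columns=["trial", "delta", "correct", "reversal"])
    tail = reversal_deltas[-config.estimate_reversals :]
    estimate = float(np.mean(tail)) if tail else delta
    hit_upper = n_at_upper > 0.5 * len(trace)
    return StaircaseResult(
        estimate=estimate,
        trace=trace,
        reversal_deltas=reversal_deltas,
        hit_upper_bound=hit_upper,
    )
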