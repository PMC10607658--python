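"""Exercise-quality metrics computed from an action log.

Four metrics summarize one scene: positioning accuracy (Puzzle), reaction
accuracy (Shooting), duration and speed.  Positioning "accuracy" is the
mean positional deviation expressed in percent of a normalized scene unit,

    A = (sum_i |x_i - x_i*| / N) * 100,

summed over the B placements and divided by the total action count N --
lower is better, which the returned metrics flag explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ActionLog

__all__ = [
    "PerformanceMetrics",
    "accuracy_positioning",
    "accuracy_reaction",
    "duration",
    "speed",
    "compute_performance",
]


@dataclass(frozen=True)
class PerformanceMetrics:
    accuracy: float          # percent
    duration: float          # seconds
    speed: float             # actions per second
    exercise: str
    accuracy_lower_is_better: bool


def accuracy_positioning(log: ActionLog) -> float:
    """Mean Euclidean placement deviation per action, in percent (lower = better)."""
    if log.exercise != "Puzzle":
        raise ValueError("positioning accuracy applies to the Puzzle exercise")
    n = log.n_actions
    if n == 0:
        raise ValueError("empty action log")
    total = 0.0
    for ev in log.events:
        if ev.kind != "placement":
            continue
        if ev.target is None or ev.placed is None:
            raise ValueError("placement event missing a position")
        total += float(np.linalg.norm(np.subtract(ev.placed, ev.target)))
    return total / n * 100.0


def accuracy_reaction(log: ActionLog) -> float:
    """Fraction of successful actions, in percent: A = K/N * 100."""
    if log.exercise != "Shooting":
        raise ValueError("reaction accuracy applies to the Shooting exercise")
    n = log.n_actions
    if n == 0:
        raise ValueError("empty action log")
    return log.n_hits / n * 100.0


def duration(log: ActionLog) -> float:
    """Exercise duration T = t_end - t_start, seconds."""
    return log.t_end - log.t_start


def speed(log: ActionLog) -> float:
    """Actions per second: S = N / T."""
    t = duration(log)
    if t == 0:
        raise ValueError("zero-duration exercise: speed undefined")
    return log.n_actions / t


def compute_performance(log: ActionLog) -> PerformanceMetrics:
    """All four metrics for one log, dispatching accuracy on exercise type."""
    if log.exercise == "Puzzle":
        acc, lower = accuracy_positioning(log), True
    else:
        acc, lower = accuracy_reaction(log), False
    return PerformanceMetrics(
        accuracy=acc,
        duration=duration(log),
        speed=speed(log),
        exercise=log.exercise,
        accuracy_lower_is_better=lower,
    )
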