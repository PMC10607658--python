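"""Shared fixtures and independent oracles for the test suite.

Oracles here are literal, loop-based transcriptions of the defining
formulas, kept deliberately separate from (and dumber than) the package
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from vrphobia import ActionEvent, ActionLog, CohortConfig, EEGRecording, SceneSpec
from vrphobia.montage import CHANNELS_21


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_positioning_accuracy(log: ActionLog) -> float:
    """Literal transcription: sum of placement deviations over N, x100."""
    total = 0.0
    for ev in log.events:
        if ev.kind == "placement":
            total += math.sqrt(
                sum((p - t) ** 2 for p, t in zip(ev.placed, ev.target))
            )
    return total / len(log.events) * 100.0


def oracle_amplitude_stats(data: np.ndarray) -> tuple[float, float, float]:
    """Literal per-channel max/mean/std (n-1) followed by channel means."""
    maxes, means, stds = [], [], []
    for row in data:
        maxes.append(max(row))
        mu = sum(row) / len(row)
        means.append(mu)
        stds.append(math.sqrt(sum((x - mu) ** 2 for x in row) / (len(row) - 1)))
    ch = len(data)
    return sum(maxes) / ch, sum(means) / ch, sum(stds) / ch


def fractional_gaussian_noise(h: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Spectral-synthesis fGn with target Hurst exponent ``h``."""
    freqs = np.fft.rfftfreq(2 * n, d=1.0)
    freqs[0] = freqs[1]
    amp = freqs ** (-(2.0 * h - 1.0) / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(freqs))
    x = np.fft.irfft(amp * np.exp(1j * phases))[:n]
    return (x - x.mean()) / x.std()


def random_action_log(rng: np.random.Generator, exercise: str = "Puzzle") -> ActionLog:
    n = int(rng.integers(3, 12))
    times = np.sort(rng.uniform(0.5, 59.0, n))
    events = []
    for ts in times:
        if exercise == "Puzzle":
            kind = "placement" if rng.random() < 0.8 else "other"
            if kind == "placement":
                target = tuple(rng.uniform(0, 1, 3))
                placed = tuple(np.array(target) + rng.normal(0, 0.1, 3))
                events.append(ActionEvent(float(ts), kind, placed=placed, target=target))
            else:
                events.append(ActionEvent(float(ts), "other"))
        else:
            events.append(ActionEvent(float(ts), "shot", success=bool(rng.random() < 0.6)))
    return ActionLog(scene_id=1 if exercise == "Puzzle" else 4, exercise=exercise,
                     events=events, t_start=0.0, t_end=60.0, participant_id="PX")


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def tiny_cohort_config() -> CohortConfig:
    """Two participants (one abnormal), short records: fast full-path runs."""
    return CohortConfig(n_participants=2, n_abnormal=1, record_duration=4.0, seed=11)


@pytest.fixture()
def synthetic_record(rng) -> EEGRecording:
    """A 21-channel, 8 s, 500 Hz record of band-limited noise."""
    fs = 500.0
    n = int(8 * fs)
    t = np.arange(n) / fs
    data = np.array([
        12.0 * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        + 5.0 * rng.standard_normal(n)
        for _ in CHANNELS_21
    ])
    return EEGRecording(data=data, sampling_rate=fs, channels=CHANNELS_21,
                        participant_id="P001", scene_id=1)


def puzzle_scene(scene_id: int = 1, environment: str = "norm") -> SceneSpec:
    return SceneSpec(scene_id, "Puzzle", environment)
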