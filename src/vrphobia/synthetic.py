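"""Synthetic study generator: participants, scenes, EEG and action logs.

The generator emulates the study conditions the pipeline is built for:
28 participants each performing two VR exercises (Puzzle, Shooting) under
three environments (norm, arachnophobia, acrophobia) -- 168 records -- with
21-channel, 500 Hz EEG per record.  A small "abnormal" subgroup (default 4
participants) is planted whose phobic-scene records show elevated band
power, depressed right-hemisphere alpha, raised right-hemisphere beta and
degraded task performance, so every downstream stage (features, statistics,
clustering) can be exercised and validated against known ground truth.

Signal model
------------
Each channel is a sum of amplitude-modulated sinusoidal carriers (theta
6 Hz, alpha 10 Hz, beta 20 Hz) scaled by per-band hemisphere gains, plus a
shared band-limited common source (mixed into every channel with
per-channel weights, giving the coherence matrices controllable structure)
and 1/f-shaped pink noise.  Amplitudes are in microvolts.  This is the
simplest model whose Welch band powers, asymmetry and coherence are
directly controllable; it makes no biophysical claim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _sig
from scipy.ndimage import gaussian_filter1d

from .io_formats import ActionEvent, ActionLog, EEGRecording, write_actions_csv, write_edf
from .montage import CHANNELS_21, hemisphere

__all__ = [
    "SceneSpec",
    "CohortConfig",
    "ParticipantProfile",
    "CohortRecord",
    "default_scenes",
    "sample_profile",
    "synthesize_eeg",
    "synthesize_actions",
    "generate_cohort",
    "export_cohort",
]

BAND_CARRIERS = {"theta": 6.0, "alpha": 10.0, "beta": 20.0}
BASE_BAND_AMPS = {"theta": 20.0, "alpha": 30.0, "beta": 15.0}  # µV
_PINK_STD = 8.0          # µV, 1/f noise
_ENVELOPE_DEPTH = 0.3    # relative amplitude-modulation depth
_COMMON_BAND = (4.0, 30.0)


@dataclass(frozen=True)
class SceneSpec:
    """One exercise x environment cell of the study design."""

    scene_id: int
    exercise: Literal["Puzzle", "Shooting"]
    environment: Literal["norm", "arachnophobia", "acrophobia"]
    n_actions: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.scene_id <= 6:
            raise ValueError("scene_id must be in 1..6")
        if self.n_actions < 1:
            raise ValueError("n_actions must be >= 1")

    @property
    def phobic(self) -> bool:
        return self.environment != "norm"


def default_scenes() -> tuple[SceneSpec, ...]:
    """The six scenes of the study design: each exercise under each environment."""
    return (
        SceneSpec(1, "Puzzle", "norm"),
        SceneSpec(2, "Puzzle", "arachnophobia"),
        SceneSpec(3, "Puzzle", "acrophobia"),
        SceneSpec(4, "Shooting", "norm"),
        SceneSpec(5, "Shooting", "arachnophobia"),
        SceneSpec(6, "Shooting", "acrophobia"),
    )


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Effect multipliers act on *power* (amplitudes are scaled by their square
    root) and apply to abnormal participants in phobic scenes only; abnormal
    participants additionally carry trait-level performance deficits in all
    scenes, mirroring a subgroup that differs throughout the session.
    """

    n_participants: int = 28
    n_abnormal: int = 4
    scenes: tuple[SceneSpec, ...] = field(default_factory=default_scenes)
    sampling_rate: float = 500.0
    n_channels: int = 21
    record_duration: float = 60.0           # seconds per scene
    seed: int = 0
    # abnormal x phobic effect sizes
    phobic_power_multiplier: float = 3.0    # theta/alpha/beta band power
    alpha_right_gain_factor: float = 0.6    # right-hemisphere alpha power
    beta_right_gain_factor: float = 1.4     # right-hemisphere beta power
    positional_noise_factor: float = 2.5    # Puzzle placement noise std
    hit_prob_factor: float = 0.55           # Shooting success probability
    # trait-level abnormal deficits (all scenes)
    trait_pace_factor: float = 2.0
    trait_noise_factor: float = 2.2
    trait_hit_decrement: float = 0.15
    participant_heterogeneity: float = 0.20  # lognormal sigma of traits

    def __post_init__(self) -> None:
        self.scenes = tuple(self.scenes)
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not 0 <= self.n_abnormal <= self.n_participants:
            raise ValueError("n_abnormal must be in [0, n_participants]")
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")
        if self.n_channels < 1 or self.n_channels > len(CHANNELS_21):
            raise ValueError(f"n_channels must be in 1..{len(CHANNELS_21)}")
        if not self.scenes:
            raise ValueError("at least one scene required")
        highest = max(max(BAND_CARRIERS.values()), _COMMON_BAND[1])
        if self.sampling_rate <= 2 * highest:
            raise ValueError(
                f"sampling_rate must exceed twice the highest synthesized "
                f"frequency ({highest} Hz)"
            )
        for name in ("phobic_power_multiplier", "alpha_right_gain_factor",
                     "beta_right_gain_factor", "positional_noise_factor",
                     "hit_prob_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def channels(self) -> tuple[str, ...]:
        return CHANNELS_21[: self.n_channels]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenes"] = [asdict(s) for s in self.scenes]
        return d


@dataclass
class ParticipantProfile:
    """Latent traits of one synthetic participant."""

    participant_id: str
    abnormal: bool
    band_amps: dict[str, float]                  # µV per band
    gains: dict[str, tuple[float, float]]        # (left, right) per band
    coupling_uv: float                           # common-source amplitude
    mixing: np.ndarray                           # per-channel source weights
    place_noise: float                           # placement noise std
    hit_prob: float
    pace: dict[str, float]                       # mean inter-action gap, s


def sample_profile(
    rng: np.random.Generator,
    participant_id: str,
    abnormal: bool,
    config: CohortConfig,
) -> ParticipantProfile:
    het = config.participant_heterogeneity
    band_amps = {b: a * rng.lognormal(0.0, 0.15) for b, a in BASE_BAND_AMPS.items()}
    gains = {
        b: (rng.lognormal(0.0, 0.05), rng.lognormal(0.0, 0.05)) for b in BAND_CARRIERS
    }
    coupling = (14.0 if abnormal else 8.0) * rng.lognormal(0.0, 0.10)
    mixing = rng.uniform(0.5, 1.0, size=config.n_channels)
    place_noise = 0.04 * rng.lognormal(0.0, het)
    hit_prob = 0.78 * rng.lognormal(0.0, 0.08)
    pace = {
        "Puzzle": 8.0 * rng.lognormal(0.0, het),
        "Shooting": 2.0 * rng.lognormal(0.0, het),
    }
    if abnormal:
        place_noise *= config.trait_noise_factor
        hit_prob -= config.trait_hit_decrement
        pace = {k: v * config.trait_pace_factor for k, v in pace.items()}
    return ParticipantProfile(
        participant_id=participant_id,
        abnormal=abnormal,
        band_amps=band_amps,
        gains=gains,
        coupling_uv=coupling,
        mixing=mixing,
        place_noise=place_noise,
        hit_prob=float(np.clip(hit_prob, 0.05, 0.98)),
        pace=pace,
    )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_envelope(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Nonnegative slow amplitude-modulation envelope with unit mean."""
    sigma = max(2.0, 0.3 * fs)  # ~0.5 Hz bandwidth at 500 Hz
    env = gaussian_filter1d(rng.standard_normal(n), sigma, mode="wrap")
    sd = env.std()
    if sd > 0:
        env = env / sd
    return np.clip(1.0 + _ENVELOPE_DEPTH * env, 0.0, None)


def synthesize_eeg(
    profile: ParticipantProfile,
    scene: SceneSpec,
    config: CohortConfig,
    rng: np.random.Generator,
) -> EEGRecording:
    """Render one scene's multichannel EEG for a participant.

    Abnormal x phobic records get all band powers multiplied by
    ``phobic_power_multiplier``, right-hemisphere alpha power scaled by
    ``alpha_right_gain_factor`` (< 1: depression) and right-hemisphere beta
    power by ``beta_right_gain_factor`` (> 1).
    """
    fs = config.sampling_rate
    n = int(round(config.record_duration * fs))
    t = np.arange(n) / fs
    channels = config.channels
    affected = profile.abnormal and scene.phobic

    common = _sig.sosfiltfilt(
        _sig.butter(4, _COMMON_BAND, btype="bandpass", fs=fs, output="sos"),
        rng.standard_normal(n),
    )
    sd = common.std()
    if sd > 0:
        common /= sd

    data = np.empty((len(channels), n))
    for ci, ch in enumerate(channels):
        side = hemisphere(ch)
        sig = profile.coupling_uv * profile.mixing[ci] * common
        sig = sig + _PINK_STD * _pink_noise(rng, n)
        for band, f0 in BAND_CARRIERS.items():
            left, right = profile.gains[band]
            gain = {"left": left, "right": right, "midline": 0.5 * (left + right)}[side]
            amp = profile.band_amps[band] * gain
            if affected:
                amp *= np.sqrt(config.phobic_power_multiplier)
                if side == "right" and band == "alpha":
                    amp *= np.sqrt(config.alpha_right_gain_factor)
                if side == "right" and band == "beta":
                    amp *= np.sqrt(config.beta_right_gain_factor)
            envelope = _slow_envelope(rng, n, fs)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sig = sig + amp * envelope * np.sin(2.0 * np.pi * f0 * t + phase)
        data[ci] = sig
    return EEGRecording(
        data=data,
        sampling_rate=fs,
        channels=channels,
        participant_id=profile.participant_id,
        scene_id=scene.scene_id,
    )


def synthesize_actions(
    profile: ParticipantProfile,
    scene: SceneSpec,
    config: CohortConfig,
    rng: np.random.Generator,
) -> ActionLog:
    """Render one scene's behavioral log.

    Puzzle: ``n_actions`` placements at random unit-cube targets with
    Gaussian positional noise (inflated for abnormal x phobic).  Shooting:
    ``n_actions`` shots with Bernoulli hits (success probability reduced
    for abnormal x phobic).  Timestamps are strictly increasing.
    """
    affected = profile.abnormal and scene.phobic
    gaps = rng.gamma(4.0, profile.pace[scene.exercise] / 4.0, scene.n_actions)
    gaps = np.maximum(gaps, 1e-3)
    timestamps = np.cumsum(gaps)
    events: list[ActionEvent] = []
    if scene.exercise == "Puzzle":
        sigma = profile.place_noise * (config.positional_noise_factor if affected else 1.0)
        for ts in timestamps:
            target = rng.uniform(0.0, 1.0, 3)
            placed = target + rng.normal(0.0, sigma, 3)
            events.append(ActionEvent(float(ts), "placement",
                                      placed=tuple(placed), target=tuple(target)))
    else:
        p = profile.hit_prob * (config.hit_prob_factor if affected else 1.0)
        p = float(np.clip(p, 0.0, 1.0))
        for ts in timestamps:
            events.append(ActionEvent(float(ts), "shot", success=bool(rng.random() < p)))
    return ActionLog(
        scene_id=scene.scene_id,
        exercise=scene.exercise,
        events=events,
        t_start=0.0,
        t_end=float(timestamps[-1] + 1.0),
        participant_id=profile.participant_id,
    )


@dataclass
class CohortRecord:
    """One participant x scene observation with its ground-truth label."""

    participant_id: str
    scene: SceneSpec
    eeg: EEGRecording | None
    actions: ActionLog
    abnormal: bool


def generate_cohort(
    config: CohortConfig | None = None,
    include_eeg: bool = True,
) -> list[CohortRecord]:
    """Generate the full synthetic study.

    Returns exactly ``n_participants x len(scenes)`` records.  The first
    ``n_abnormal`` participants carry the planted abnormal traits.  Output
    is bit-identical for identical seeds; per-record random streams are
    spawned independently, so ``include_eeg=False`` (a fast path when only
    behavioral metrics are needed) leaves the action logs unchanged.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    part_seqs = root.spawn(config.n_participants)
    records: list[CohortRecord] = []
    for i, pseq in enumerate(part_seqs):
        pid = f"P{i + 1:03d}"
        abnormal = i < config.n_abnormal
        streams = pseq.spawn(1 + 2 * len(config.scenes))
        profile = sample_profile(np.random.default_rng(streams[0]), pid, abnormal, config)
        for j, scene in enumerate(config.scenes):
            eeg_rng = np.random.default_rng(streams[1 + 2 * j])
            act_rng = np.random.default_rng(streams[2 + 2 * j])
            eeg = synthesize_eeg(profile, scene, config, eeg_rng) if include_eeg else None
            actions = synthesize_actions(profile, scene, config, act_rng)
            records.append(CohortRecord(pid, scene, eeg, actions, abnormal))
    return records


def export_cohort(
    records: Sequence[CohortRecord],
    out_dir: str | Path,
    config: CohortConfig | None = None,
) -> Path:
    """Write a cohort to disk: EDF per record, CSV action logs, a manifest
    CSV and (optionally) the generating config as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = f"{rec.participant_id}_scene{rec.scene.scene_id}"
        edf_path = ""
        if rec.eeg is not None:
            edf_path = f"{stem}.edf"
            write_edf(rec.eeg, out_dir / edf_path)
        log_path = f"{stem}_actions.csv"
        write_actions_csv(rec.actions, out_dir / log_path)
        rows.append({
            "participant_id": rec.participant_id,
            "scene_id": rec.scene.scene_id,
            "exercise": rec.scene.exercise,
            "environment": rec.scene.environment,
            "abnormal": int(rec.abnormal),
            "edf_path": edf_path,
            "actions_path": log_path,
        })
    import csv as _csv

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = _csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    if config is not None:
        (out_dir / "cohort_config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True)
        )
    return manifest
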