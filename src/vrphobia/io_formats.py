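"""Containers and file formats: EEG records (EDF), action logs (CSV),
channel selection and amplitude-based noise rejection.

EDF is the clinical container used by devices like the Neuron-Spectrum
family.  Reading goes through MNE; writing uses a small 16-bit EDF writer
(one-second data records, per-channel physical scaling).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _sig

from .montage import CHANNELS_18

__all__ = [
    "EEGRecording",
    "ActionEvent",
    "ActionLog",
    "write_edf",
    "read_edf",
    "write_actions_csv",
    "read_actions_csv",
    "select_channels",
    "reject_noisy_segments",
    "CleaningResult",
    "bandpass_filter",
]


@dataclass
class EEGRecording:
    """One participant x scene multichannel EEG signal in microvolts."""

    data: np.ndarray                # (n_channels, n_samples), µV
    sampling_rate: float            # Hz
    channels: tuple[str, ...]
    participant_id: str = ""
    scene_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class ActionEvent:
    """A single behavioral event inside one scene."""

    timestamp: float                         # seconds from scene start
    kind: Literal["placement", "shot", "other"]
    placed: tuple[float, ...] | None = None  # normalized scene units
    target: tuple[float, ...] | None = None
    success: bool | None = None              # shots only


@dataclass
class ActionLog:
    """Per-scene behavioral log: N actions between t_start and t_end."""

    scene_id: int
    exercise: Literal["Puzzle", "Shooting"]
    events: list[ActionEvent] = field(default_factory=list)
    t_start: float = 0.0
    t_end: float = 0.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")
        for ev in self.events:
            if not (self.t_start <= ev.timestamp <= self.t_end):
                raise ValueError("event timestamp outside [t_start, t_end]")
            if ev.kind == "placement" and (ev.placed is None or ev.target is None):
                raise ValueError("placement events need placed and target positions")

    @property
    def n_actions(self) -> int:
        """N: total number of user actions."""
        return len(self.events)

    @property
    def n_placements(self) -> int:
        """B: number of placed objects."""
        return sum(ev.kind == "placement" for ev in self.events)

    @property
    def n_hits(self) -> int:
        """K: number of successful actions."""
        return sum(bool(ev.success) for ev in self.events)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad_field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        text = text[:width]
    return text.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    Physical scaling is per channel (actual min/max), so the quantization
    step is (max-min)/65535.  If the signal length is not a whole number of
    seconds the final record is zero-padded.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_sig = rec.n_channels
    n_rec = math.ceil(rec.n_samples / spr)
    data = np.zeros((n_sig, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _pad_field("0", 8),
        _pad_field(rec.participant_id or "X", 80),
        _pad_field(f"scene {rec.scene_id}", 80),
        _pad_field("01.01.01", 8),          # fixed date/time: reproducible files
        _pad_field("00.00.00", 8),
        _pad_field(256 * (1 + n_sig), 8),
        _pad_field("", 44),
        _pad_field(n_rec, 8),
        _pad_field(1, 8),                   # record duration, seconds
        _pad_field(n_sig, 4),
    ])

    def sig_fields(values, width):
        return b"".join(_pad_field(v, width) for v in values)

    header += sig_fields(rec.channels, 16)
    header += sig_fields([""] * n_sig, 80)
    header += sig_fields(["uV"] * n_sig, 8)
    header += sig_fields([f"{v:.6g}"[:8] for v in pmin], 8)
    header += sig_fields([f"{v:.6g}"[:8] for v in pmax], 8)
    header += sig_fields([dmin] * n_sig, 8)
    header += sig_fields([dmax] * n_sig, 8)
    header += sig_fields(["HP:0.5Hz LP:70Hz"] * n_sig, 80)
    header += sig_fields([spr] * n_sig, 8)
    header += sig_fields([""] * n_sig, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path


def _read_edf_header(path: Path) -> dict:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        patient = head[8:88].decode("ascii", "replace").strip()
        recording = head[88:168].decode("ascii", "replace").strip()
        try:
            n_sig = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header") from exc
        labels_raw = fh.read(16 * n_sig)
    labels = tuple(
        labels_raw[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(n_sig)
    )
    return {"patient": patient, "recording": recording, "labels": labels}


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (data in µV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_edf_header(path)
    if len(set(meta["labels"])) != len(meta["labels"]):
        raise ValueError(f"{path}: duplicate channel labels in EDF header")

    import mne  # deferred: heavy import

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    scene_id = 0
    rec_field = meta["recording"]
    if rec_field.startswith("scene"):
        try:
            scene_id = int(rec_field.split()[-1])
        except ValueError:
            pass
    return EEGRecording(
        data=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        participant_id=meta["patient"],
        scene_id=scene_id,
    )


# ---------------------------------------------------------------------------
# Action log CSV
# ---------------------------------------------------------------------------

_ACTION_COLUMNS = [
    "participant_id", "scene_id", "exercise", "t_start", "t_end",
    "timestamp", "kind",
    "placed_x", "placed_y", "placed_z",
    "target_x", "target_y", "target_z",
    "success",
]


def write_actions_csv(log: ActionLog, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_ACTION_COLUMNS)
        writer.writeheader()
        for ev in log.events:
            row = {
                "participant_id": log.participant_id,
                "scene_id": log.scene_id,
                "exercise": log.exercise,
                "t_start": repr(float(log.t_start)),
                "t_end": repr(float(log.t_end)),
                "timestamp": repr(float(ev.timestamp)),
                "kind": ev.kind,
                "success": "" if ev.success is None else int(ev.success),
            }
            for name, pos in (("placed", ev.placed), ("target", ev.target)):
                for axis, value in zip("xyz", pos or ()):
                    row[f"{name}_{axis}"] = repr(float(value))
            writer.writerow(row)
    return path


def read_actions_csv(path: str | Path) -> ActionLog:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"{path}: empty action log")

    def pos(row, name):
        vals = [row.get(f"{name}_{axis}", "") for axis in "xyz"]
        if all(v == "" for v in vals):
            return None
        return tuple(float(v) for v in vals if v != "")

    events = [
        ActionEvent(
            timestamp=float(r["timestamp"]),
            kind=r["kind"],
            placed=pos(r, "placed"),
            target=pos(r, "target"),
            success=None if r.get("success", "") == "" else bool(int(r["success"])),
        )
        for r in rows
    ]
    first = rows[0]
    return ActionLog(
        scene_id=int(first["scene_id"]),
        exercise=first["exercise"],
        events=events,
        t_start=float(first["t_start"]),
        t_end=float(first["t_end"]),
        participant_id=first["participant_id"],
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def select_channels(
    rec: EEGRecording, channels: Sequence[str] = CHANNELS_18
) -> EEGRecording:
    """Project onto the analysis channels, in canonical order.

    A pure projection: sample values are untouched.  Raises if any required
    channel is missing.
    """
    missing = [ch for ch in channels if ch not in rec.channels]
    if missing:
        raise ValueError(f"recording lacks required channel(s): {', '.join(missing)}")
    idx = [rec.channels.index(ch) for ch in channels]
    return EEGRecording(
        data=rec.data[idx],
        sampling_rate=rec.sampling_rate,
        channels=tuple(channels),
        participant_id=rec.participant_id,
        scene_id=rec.scene_id,
    )


@dataclass
class CleaningResult:
    """Outcome of amplitude-based noise rejection on one recording."""

    record: EEGRecording | None
    rejected: bool
    clean_fraction: float
    removed_windows: list[int]
    n_windows: int


def reject_noisy_segments(
    rec: EEGRecording,
    amplitude_threshold: float = 200.0,
    min_clean_fraction: float = 0.5,
    window_seconds: float = 1.0,
) -> CleaningResult:
    """Excise fixed-length windows whose peak |amplitude| exceeds a threshold.

    The record is split into consecutive windows (the final, possibly
    shorter, remainder counts as a window).  A window is removed if *any*
    channel exceeds ``amplitude_threshold`` µV in absolute value.  If the
    surviving fraction of samples falls below ``min_clean_fraction`` the
    whole record is flagged as rejected -- a reported outcome, not an error.
    """
    if not amplitude_threshold > 0:
        raise ValueError("amplitude_threshold must be positive")
    win = max(1, int(round(window_seconds * rec.sampling_rate)))
    n = rec.n_samples
    n_windows = math.ceil(n / win)
    keep_masks, removed = [], []
    for w in range(n_windows):
        chunk = rec.data[:, w * win : min((w + 1) * win, n)]
        if np.abs(chunk).max() > amplitude_threshold:
            removed.append(w)
        else:
            keep_masks.append((w * win, min((w + 1) * win, n)))
    kept = sum(b - a for a, b in keep_masks)
    clean_fraction = kept / n if n else 0.0
    if clean_fraction < min_clean_fraction:
        return CleaningResult(None, True, clean_fraction, removed, n_windows)
    if not removed:
        return CleaningResult(rec, False, 1.0, [], n_windows)
    data = np.concatenate([rec.data[:, a:b] for a, b in keep_masks], axis=1)
    clean = EEGRecording(
        data=data,
        sampling_rate=rec.sampling_rate,
        channels=rec.channels,
        participant_id=rec.participant_id,
        scene_id=rec.scene_id,
    )
    return CleaningResult(clean, False, clean_fraction, removed, n_windows)


def bandpass_filter(
    rec: EEGRecording, low: float = 0.5, high: float = 70.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass matching the acquisition device band."""
    nyq = rec.sampling_rate / 2
    if not 0 < low < high < nyq:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = _sig.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate,
                      output="sos")
    return EEGRecording(
        data=_sig.sosfiltfilt(sos, rec.data, axis=1),
        sampling_rate=rec.sampling_rate,
        channels=rec.channels,
        participant_id=rec.participant_id,
        scene_id=rec.scene_id,
    )
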