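"""Per-channel and aggregated EEG characteristics.

For each channel: amplitude statistics (max, mean, sample standard
deviation), the rescaled-range Hurst exponent, and Welch band power in the
theta (4-8 Hz), alpha (8-13 Hz) and beta (13-30 Hz) rhythms.  Aggregates
are arithmetic means over channels.  From the band powers of homologous
right-left electrode pairs the interhemispheric asymmetry index

    IHA(h) = (PSD_r(h) - PSD_l(h)) / (PSD_r(h) + PSD_l(h)) * 100   [%]

is derived, bounded in [-100, 100] and antisymmetric under swapping the
pair.

Hurst estimator
---------------
Classical rescaled-range analysis: for a ladder of window sizes n (powers
of two from 16 to N/4) the series is split into blocks, each block's
mean-adjusted cumulative deviates give a range R and the block standard
deviation S; block-averaged R/S is regressed on n in log-log coordinates.
The Anis-Lloyd-Peters finite-sample expectation E[R/S] is divided out
before the fit (H = 1/2 + slope of log(R/S / E[R/S])), which removes the
well-known upward small-sample bias and calibrates the estimator to 0.5
for memoryless (iid / Brownian-increment) series.  Estimates are reported
clipped to [0, 1.05].
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.special import gammaln

from .io_formats import ActionLog, EEGRecording
from .montage import IHA_PAIRS
from .performance import compute_performance

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CohortRecord

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

__all__ = [
    "BANDS",
    "amplitude_features",
    "hurst_exponent",
    "expected_rs",
    "welch_psd",
    "welch_band_power",
    "iha",
    "iha_profile",
    "compute_record_features",
    "features_table",
]

DEVICE_BAND = (0.5, 70.0)       # acquisition high/low-pass corner frequencies
WELCH_SECONDS = 2.0             # Hann windows, 50% overlap, linear detrend


# ---------------------------------------------------------------------------
# Amplitude statistics
# ---------------------------------------------------------------------------

def amplitude_features(rec: EEGRecording) -> tuple[pd.DataFrame, pd.Series]:
    """Per-channel (max, mean, sample std) amplitudes and their channel means.

    Returns ``(per_channel, aggregates)`` where ``per_channel`` is indexed
    by channel label with columns ``amp_max``, ``amp_mean``, ``amp_std``
    (µV) and ``aggregates`` holds the arithmetic means over channels.
    """
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    per = pd.DataFrame(
        {
            "amp_max": rec.data.max(axis=1),
            "amp_mean": rec.data.mean(axis=1),
            "amp_std": rec.data.std(axis=1, ddof=1),
        },
        index=list(rec.channels),
    )
    return per, per.mean(axis=0)


# ---------------------------------------------------------------------------
# Hurst exponent (rescaled range)
# ---------------------------------------------------------------------------

def expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expectation of the R/S statistic for iid series."""
    i = np.arange(1, n)
    tail = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        front = np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2.0)
    return (n - 0.5) / n * front * tail


def _rs_average(x: np.ndarray, size: int) -> float:
    m = (len(x) // size) * size
    blocks = x[:m].reshape(-1, size)
    dev = np.cumsum(blocks - blocks.mean(axis=1, keepdims=True), axis=1)
    rng_ = dev.max(axis=1) - dev.min(axis=1)
    std = blocks.std(axis=1, ddof=1)
    ok = std > 0
    if not ok.any():
        raise ValueError("constant signal: R/S undefined")
    return float(np.mean(rng_[ok] / std[ok]))


def hurst_exponent(x: Sequence[float], min_window: int = 16) -> float:
    """Rescaled-range Hurst exponent of a 1-D series, clipped to [0, 1.05]."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    n = len(x)
    if n < 256:
        raise ValueError("need at least 256 samples for a stable R/S ladder")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: Hurst exponent undefined")
    sizes = []
    size = min_window
    while size <= n // 4:
        sizes.append(size)
        size *= 2
    rs = np.array([_rs_average(x, s) for s in sizes])
    exp = np.array([expected_rs(s) for s in sizes])
    slope = np.polyfit(np.log(sizes), np.log(rs / exp), 1)[0]
    return float(np.clip(0.5 + slope, 0.0, 1.05))


# ---------------------------------------------------------------------------
# Welch band power
# ---------------------------------------------------------------------------

def _welch_params(n_samples: int, fs: float) -> tuple[int, int]:
    nperseg = min(int(round(WELCH_SECONDS * fs)), n_samples)
    return nperseg, nperseg // 2


def welch_psd(rec: EEGRecording) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of every channel: (freqs, psd[channel, freq]) in µV²/Hz."""
    nperseg, noverlap = _welch_params(rec.n_samples, rec.sampling_rate)
    freqs, psd = _sig.welch(
        rec.data, fs=rec.sampling_rate, window="hann",
        nperseg=nperseg, noverlap=noverlap, detrend="linear", axis=-1,
    )
    return freqs, psd


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return mask


def welch_band_power(
    rec: EEGRecording, band: str | tuple[float, float]
) -> tuple[pd.Series, float]:
    """Band-averaged Welch PSD per channel plus the channel-mean aggregate.

    ``band`` is a rhythm name (``'theta'``/``'alpha'``/``'beta'``) or an
    explicit (low, high) pair, which must lie inside the device pass band
    (0.5-70 Hz).  Power is reported as mean spectral density over the
    band's bins (µV²/Hz); only ratios and comparisons are used downstream,
    so the density-vs-integral convention cancels.
    """
    edges = BANDS[band] if isinstance(band, str) else tuple(band)
    if not (DEVICE_BAND[0] <= edges[0] < edges[1] <= DEVICE_BAND[1]):
        raise ValueError(f"band {edges} outside device range {DEVICE_BAND}")
    nperseg, _ = _welch_params(rec.n_samples, rec.sampling_rate)
    if rec.n_samples < nperseg + nperseg // 2:
        raise ValueError("record too short for two Welch windows")
    freqs, psd = welch_psd(rec)
    mask = _band_slice(freqs, edges)
    per = pd.Series(psd[:, mask].mean(axis=1), index=list(rec.channels))
    return per, float(per.mean())


# ---------------------------------------------------------------------------
# Interhemispheric asymmetry
# ---------------------------------------------------------------------------

def iha(psd_right: float, psd_left: float) -> float:
    """Normalized right-minus-left band-power difference, percent."""
    if psd_right < 0 or psd_left < 0:
        raise ValueError("band powers must be nonnegative")
    total = psd_right + psd_left
    if total == 0:
        raise ValueError("zero total band power: IHA undefined")
    return (psd_right - psd_left) / total * 100.0


def iha_profile(
    rec: EEGRecording,
    pairs: Sequence[tuple[str, str]] = IHA_PAIRS,
    bands: Mapping[str, tuple[float, float]] = BANDS,
) -> pd.DataFrame:
    """IHA for every derivation pair x band; rows = "R-L" pair names."""
    freqs, psd = welch_psd(rec)
    idx = {ch: i for i, ch in enumerate(rec.channels)}
    out = {}
    for band_name, edges in bands.items():
        mask = _band_slice(freqs, edges)
        band_power = psd[:, mask].mean(axis=1)
        col = []
        for right, left in pairs:
            if right not in idx or left not in idx:
                raise ValueError(f"pair {right}-{left} not present in recording")
            col.append(iha(band_power[idx[right]], band_power[idx[left]]))
        out[band_name] = col
    return pd.DataFrame(out, index=[f"{r}-{l}" for r, l in pairs])


# ---------------------------------------------------------------------------
# Tidy feature table
# ---------------------------------------------------------------------------

def compute_record_features(
    eeg: EEGRecording | None,
    actions: ActionLog,
    include_hurst: bool = True,
) -> dict[str, float]:
    """One tidy row: performance metrics plus (if EEG given) EEG features."""
    perf = compute_performance(actions)
    row: dict[str, float] = {
        "A": perf.accuracy,
        "T": perf.duration,
        "S": perf.speed,
    }
    if eeg is None:
        return row
    _, agg = amplitude_features(eeg)
    row["Amax"] = float(agg["amp_max"])
    row["Amean"] = float(agg["amp_mean"])
    row["Astd"] = float(agg["amp_std"])
    if include_hurst:
        row["H"] = float(np.mean([hurst_exponent(ch) for ch in eeg.data]))
    freqs, psd = welch_psd(eeg)
    for band_name, edges in BANDS.items():
        mask = _band_slice(freqs, edges)
        row[f"PSD_{band_name}"] = float(psd[:, mask].mean())
    profile = iha_profile(eeg)
    for pair in profile.index:
        for band_name in BANDS:
            row[f"IHA_{band_name}_{pair}"] = float(profile.loc[pair, band_name])
    return row


def features_table(
    records: "Iterable[CohortRecord]",
    include_hurst: bool = True,
    preprocess=None,
) -> pd.DataFrame:
    """Feature rows for a cohort: one row per participant x scene.

    ``preprocess`` is an optional callable applied to each EEG record
    (e.g. channel selection + noise rejection); returning ``None`` drops
    the record from the table.
    """
    rows = []
    for rec in records:
        eeg = rec.eeg
        if eeg is not None and preprocess is not None:
            eeg = preprocess(eeg)
            if eeg is None:
                continue
        row = {
            "participant_id": rec.participant_id,
            "scene_id": rec.scene.scene_id,
            "exercise": rec.scene.exercise,
            "environment": rec.scene.environment,
            "abnormal": int(rec.abnormal),
        }
        row.update(compute_record_features(eeg, rec.actions, include_hurst))
        rows.append(row)
    return pd.DataFrame(rows)
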