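"""Magnitude-squared coherence between channel pairs, surrogate-masked
coherence matrices and group summaries.

For two channels x, y the magnitude-squared coherence is

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f)),

estimated from multi-window Welch cross- and auto-spectra (2 s Hann
windows, 50% overlap, per-window linear detrend -- the same parameters
used for band power, so spectra are internally consistent).  A record's
coherence matrix stores, in the strict upper triangle, the mean coherence
over the analysis range (default 4-30 Hz, theta through beta) for each
channel pair -- but only where that value is statistically reliable:
each pair's observed value must exceed the (1 - alpha) quantile of a null
distribution built from circular phase-randomized surrogates of the second
channel.  Everything else (non-significant pairs, the diagonal and the
lower triangle) is NaN.

For efficiency the surrogate null is built from a per-channel surrogate
pool: ``surrogate_count`` phase-randomized copies of each channel are
spectrally decomposed once, and the null statistic for pair (x, y) is the
band-mean coherence of the real x against each surrogate of y.  This is
the same null (independent signals with the observed spectra) at a cost of
O(channels) rather than O(pairs) surrogate transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .io_formats import EEGRecording

__all__ = [
    "msc",
    "band_mean_coherence",
    "phase_randomize",
    "CoherenceMatrix",
    "coherence_matrix",
    "GroupCoherenceSummary",
    "group_mean_and_deviation",
    "plot_coherence_heatmap",
]

ANALYSIS_BAND = (4.0, 30.0)
WELCH_SECONDS = 2.0


def _welch_params(n_samples: int, fs: float) -> tuple[int, int]:
    nperseg = min(int(round(WELCH_SECONDS * fs)), n_samples)
    return nperseg, nperseg // 2


def _n_windows(n_samples: int, nperseg: int, noverlap: int) -> int:
    step = nperseg - noverlap
    return (n_samples - noverlap) // step


def msc(
    x: Sequence[float],
    y: Sequence[float],
    sampling_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence spectrum of two equal-length signals.

    Returns ``(freqs, C)`` with C(f) in [0, 1].  Requires at least four
    Welch windows: with a single window the estimator is identically 1
    regardless of the inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signals must be 1-D and of equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance signal: coherence undefined")
    nperseg, noverlap = _welch_params(len(x), sampling_rate)
    if _n_windows(len(x), nperseg, noverlap) < 4:
        raise ValueError("need at least 4 Welch windows for coherence")
    freqs, coh = _sig.coherence(
        x, y, fs=sampling_rate, window="hann",
        nperseg=nperseg, noverlap=noverlap, detrend="linear",
    )
    return freqs, coh


def band_mean_coherence(
    x: Sequence[float],
    y: Sequence[float],
    sampling_rate: float,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Mean magnitude-squared coherence over the analysis frequency range."""
    freqs, coh = msc(x, y, sampling_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return float(coh[mask].mean())


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Circular phase-randomized surrogate: same amplitude spectrum,
    uniformly random phases (DC and Nyquist kept real)."""
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(spec))
    phases[0] = 0.0
    if len(x) % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=len(x))


# -- vectorized spectral core ------------------------------------------------

def _segment_ffts(
    data: np.ndarray, fs: float, nperseg: int, noverlap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed, linearly detrended segment FFTs: (ch, window, freq)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    step = nperseg - noverlap
    k = (data.shape[-1] - noverlap) // step
    idx = np.arange(nperseg)[None, :] + step * np.arange(k)[:, None]
    segs = _sig.detrend(data[:, idx], axis=-1, type="linear")
    win = _sig.get_window("hann", nperseg)
    return np.fft.rfft(segs * win, axis=-1), np.fft.rfftfreq(nperseg, 1.0 / fs)


def _msc_from_ffts(zx: np.ndarray, zy: np.ndarray) -> np.ndarray:
    pxy = np.mean(np.conj(zx) * zy, axis=0)
    pxx = np.mean(np.abs(zx) ** 2, axis=0)
    pyy = np.mean(np.abs(zy) ** 2, axis=0)
    return np.abs(pxy) ** 2 / (pxx * pyy)


@dataclass
class CoherenceMatrix:
    """Upper-triangular masked mean-coherence matrix for one record."""

    values: np.ndarray                  # (CH, CH), NaN except significant pairs
    channels: tuple[str, ...]
    band: tuple[float, float]
    participant_id: str = ""
    scene_id: int = 0

    def __post_init__(self) -> None:
        ch = len(self.channels)
        if self.values.shape != (ch, ch):
            raise ValueError("matrix shape must match channel count")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def coherence_matrix(
    rec: EEGRecording,
    surrogate_count: int = 100,
    alpha_level: float = 0.05,
    band: tuple[float, float] = ANALYSIS_BAND,
    rng: np.random.Generator | int | None = None,
) -> CoherenceMatrix:
    """Surrogate-masked mean-coherence matrix of a multichannel record.

    For each unordered channel pair the band-mean coherence is kept only
    if it exceeds the empirical (1 - alpha_level) quantile of
    ``surrogate_count`` phase-randomized null values; otherwise the entry
    is NaN, as are the diagonal and lower triangle.
    """
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must be in (0, 1)")
    needed = int(np.ceil(1.0 / alpha_level)) - 1
    if surrogate_count < needed:
        raise ValueError(
            f"surrogate_count {surrogate_count} cannot resolve the "
            f"{1 - alpha_level:.3g} quantile; need >= {needed}"
        )
    rng = np.random.default_rng(rng)
    fs = rec.sampling_rate
    nperseg, noverlap = _welch_params(rec.n_samples, fs)
    if _n_windows(rec.n_samples, nperseg, noverlap) < 4:
        raise ValueError("record too short: need at least 4 Welch windows")

    z, freqs = _segment_ffts(rec.data, fs, nperseg, noverlap)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")

    ch = rec.n_channels
    # surrogate pool: phase-randomized copies of each channel, decomposed once
    z_surr = []
    for c in range(ch):
        pool = np.array([phase_randomize(rec.data[c], rng) for _ in range(surrogate_count)])
        z_surr.append(_segment_ffts(pool, fs, nperseg, noverlap)[0])

    values = np.full((ch, ch), np.nan)
    for i in range(ch):
        for j in range(i + 1, ch):
            observed = float(_msc_from_ffts(z[i], z[j])[mask].mean())
            null = np.array(
                [_msc_from_ffts(z[i], z_surr[j][s])[mask].mean()
                 for s in range(surrogate_count)]
            )
            threshold = float(np.quantile(null, 1.0 - alpha_level, method="higher"))
            if observed > threshold:
                values[i, j] = observed
    return CoherenceMatrix(
        values=values,
        channels=rec.channels,
        band=band,
        participant_id=rec.participant_id,
        scene_id=rec.scene_id,
    )


@dataclass
class GroupCoherenceSummary:
    """Entrywise NaN-aware mean matrix of a group plus per-record deviations."""

    mean: CoherenceMatrix
    deviations: list[np.ndarray]
    group_size: int

    @property
    def vmin(self) -> float:
        vals = self.mean.values[self.mean.defined]
        return float(vals.min()) if vals.size else float("nan")

    @property
    def vmax(self) -> float:
        vals = self.mean.values[self.mean.defined]
        return float(vals.max()) if vals.size else float("nan")


def group_mean_and_deviation(
    matrices: Sequence[CoherenceMatrix],
) -> GroupCoherenceSummary:
    """Mean coherence matrix over a group and each record's deviation from it.

    The mean is taken entrywise over the records where the entry is
    defined; deviations MC_i - mean are defined where both are.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    channels = matrices[0].channels
    for m in matrices[1:]:
        if m.channels != channels:
            raise ValueError("matrices have inconsistent channel ordering")
    stack = np.array([m.values for m in matrices])
    counts = np.sum(~np.isnan(stack), axis=0)
    totals = np.nansum(stack, axis=0)
    mean_vals = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    mean = CoherenceMatrix(
        values=mean_vals, channels=channels, band=matrices[0].band
    )
    deviations = [m.values - mean_vals for m in matrices]
    return GroupCoherenceSummary(mean=mean, deviations=deviations,
                                 group_size=len(matrices))


def plot_coherence_heatmap(
    matrix: CoherenceMatrix, path, title: str = ""
):
    """Render a matrix as a heatmap PNG; the title carries the min/max of
    the defined entries."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    vals = matrix.values[matrix.defined]
    headline = (
        f"min={vals.min():.3f} max={vals.max():.3f}" if vals.size else "no significant pairs"
    )
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(matrix.values, vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(matrix.channels)), matrix.channels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.channels)), matrix.channels, fontsize=7)
    ax.set_title(f"{title} ({headline})" if title else headline)
    fig.colorbar(im, ax=ax, label="mean coherence")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
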