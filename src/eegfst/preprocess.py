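"""Band decomposition, segmentation and the Gaussianity audit.

EEG rhythms are narrow frequency bands with distinct behavioural
correlates; the analysis decomposes each channel into the five classical
bands with zero-phase Butterworth band-passes, then cuts the band signals
into fixed-length windows from which differential entropy is computed
downstream.  Because the differential-entropy closed form assumes Gaussian
segments, a Kolmogorov-Smirnov audit measures how often that assumption
holds on the actual band-filtered windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import signal, stats

from .io_layouts import RawTrial

__all__ = [
    "DEFAULT_BANDS",
    "BAND_NAMES",
    "BandSet",
    "SegmentSet",
    "FilterBank",
    "design_filter_bank",
    "apply_filter_bank",
    "segment",
    "gaussianity_rate",
]

#: The five classical EEG rhythms, Hz: delta, theta, alpha, beta, gamma.
DEFAULT_BANDS: Tuple[Tuple[float, float], ...] = (
    (1.0, 4.0),
    (4.0, 8.0),
    (8.0, 13.0),
    (13.0, 30.0),
    (30.0, 50.0),
)

BAND_NAMES: Tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Band-pass order used throughout (applied forward-backward, so the
#: effective magnitude response is the squared order-3 response).
DEFAULT_ORDER = 3


@dataclass
class BandSet:
    """Band-decomposed trial: ``data`` is (bands, channels, time)."""

    data: np.ndarray
    band_edges: Tuple[Tuple[float, float], ...]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("BandSet data must be (bands, channels, time)")
        if self.data.shape[0] != len(self.band_edges):
            raise ValueError("band axis length does not match band edges")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]


@dataclass
class SegmentSet:
    """Windowed band signals: ``data`` is (segments, bands, channels, n)."""

    data: np.ndarray
    window_s: float
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("SegmentSet data must be (segments, bands, channels, samples)")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def samples_per_segment(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class FilterBank:
    """Zero-phase Butterworth band-pass bank (one SOS design per band)."""

    sos: Tuple[np.ndarray, ...]
    band_edges: Tuple[Tuple[float, float], ...]
    fs: float
    order: int

    def __len__(self) -> int:
        return len(self.sos)

    def magnitude(self, band: int, freqs_hz: np.ndarray) -> np.ndarray:
        """Effective (forward-backward) magnitude response at ``freqs_hz``."""
        w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / self.fs
        _, h = signal.sosfreqz(self.sos[band], worN=w)
        return np.abs(h) ** 2  # filtfilt squares the magnitude response


def design_filter_bank(
    fs: float,
    band_edges: Sequence[Tuple[float, float]] = DEFAULT_BANDS,
    order: int = DEFAULT_ORDER,
) -> FilterBank:
    """Design one Butterworth band-pass per rhythm.

    Each design is validated numerically: the effective gain must be at
    least 0.9 at the band's geometric-centre frequency and at most 0.1 at
    both neighbouring bands' centres.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    edges = tuple((float(lo), float(hi)) for lo, hi in band_edges)
    nyq = fs / 2.0
    for i, (lo, hi) in enumerate(edges):
        if not (0.0 < lo < hi):
            raise ValueError(f"band {i} ({lo}-{hi} Hz): edges must satisfy 0 < low < high")
        if hi >= nyq:
            raise ValueError(
                f"band {i} ({lo}-{hi} Hz): high edge must be below the Nyquist rate {nyq} Hz"
            )
    sos = tuple(
        signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
        for lo, hi in edges
    )
    bank = FilterBank(sos=sos, band_edges=edges, fs=fs, order=order)
    centers = np.array([np.sqrt(lo * hi) for lo, hi in edges])
    for i in range(len(edges)):
        gain_in = bank.magnitude(i, centers[i : i + 1])[0]
        if gain_in < 0.9:
            raise ValueError(
                f"band {i} design too narrow: centre-frequency gain {gain_in:.3f} < 0.9"
            )
        for j in (i - 1, i + 1):
            if 0 <= j < len(edges):
                leak = bank.magnitude(i, centers[j : j + 1])[0]
                if leak > 0.1:
                    raise ValueError(
                        f"band {i} leaks into band {j}: gain {leak:.3f} > 0.1"
                    )
    return bank


def apply_filter_bank(trial: RawTrial, bank: FilterBank) -> BandSet:
    """Decompose a trial into its rhythm bands (zero-phase, same length)."""
    if trial.fs != bank.fs:
        raise ValueError(
            f"trial sampled at {trial.fs} Hz but bank designed for {bank.fs} Hz"
        )
    x = trial.samples
    out = np.empty((len(bank), x.shape[0], x.shape[1]))
    for i, sos in enumerate(bank.sos):
        out[i] = signal.sosfiltfilt(sos, x, axis=-1)
    return BandSet(data=out, band_edges=bank.band_edges, fs=bank.fs)


def segment(bandset: BandSet, window_s: float = 0.5, skip_s: float = 0.0) -> SegmentSet:
    """Cut non-overlapping windows after dropping the first ``skip_s`` seconds.

    For the DEAP geometry (63-s trials at 128 Hz, 0.5-s windows) this yields
    126 segments of 64 samples from the full trial, or 120 segments of the
    emotional portion when the 3-s baseline is skipped.  A trailing partial
    window is discarded so every segment has exactly ``n`` samples.
    """
    if skip_s < 0:
        raise ValueError("skip_s must be >= 0")
    n_f = bandset.fs * window_s
    n = int(round(n_f))
    if n <= 0 or abs(n_f - n) > 1e-9:
        raise ValueError(
            f"window of {window_s}s at {bandset.fs} Hz is not a positive integer sample count"
        )
    start = int(round(bandset.fs * skip_s))
    remaining = bandset.data.shape[2] - start
    if remaining < n:
        raise ValueError(
            f"window ({n} samples) longer than the signal remaining after skip ({remaining})"
        )
    l = remaining // n
    x = bandset.data[:, :, start : start + l * n]
    # (bands, channels, l, n) -> (l, bands, channels, n)
    segs = x.reshape(x.shape[0], x.shape[1], l, n).transpose(2, 0, 1, 3)
    return SegmentSet(data=np.ascontiguousarray(segs), window_s=window_s, fs=bandset.fs)


def gaussianity_rate(
    segments: Iterable[np.ndarray],
    alpha: float = 0.05,
    estimated_params: bool = True,
) -> float:
    """Fraction of segments for which a KS normality test does not reject.

    Each segment is tested against a normal law; with ``estimated_params``
    (default) the null mean and standard deviation are the segment's own
    moment estimates, matching how the audit is used on band-filtered EEG
    windows.  Zero-variance segments cannot be normal and count as
    rejections (with a warning).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    seg_list: List[np.ndarray] = [np.asarray(s, dtype=np.float64).ravel() for s in segments]
    if not seg_list:
        raise ValueError("no segments given")
    passed = 0
    for s in seg_list:
        if s.size < 8:
            raise ValueError("segments must have at least 8 samples")
        sd = s.std()
        if sd == 0.0:
            warnings.warn("zero-variance segment counted as rejecting normality")
            continue
        if estimated_params:
            res = stats.kstest(s, "norm", args=(s.mean(), sd))
        else:
            res = stats.kstest(s, "norm")
        if res.pvalue > alpha:
            passed += 1
    return passed / len(seg_list)
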