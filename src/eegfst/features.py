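"""Differential-entropy features, baseline correction and 4D assembly.

For a Gaussian segment X ~ N(mu, sigma^2) the differential entropy has the
closed form

    H(X) = 1/2 * log(2*pi*e*sigma^2)   (nats)

so DE is a calibrated log-power feature per (band, channel, window).  By
Parseval's theorem the same value can be computed from the discrete Fourier
energy spectrum P = sum_k |X_k|^2 / N of the segment:

    H = 1/2 * log(P) + 1/2 * log(2*pi*e / N)

Both routes are implemented and agree to floating-point precision; the
spectral identity is used as a numerical cross-check in the tests.

The per-trial feature tensor (segments x bands x channels) is
baseline-corrected by subtracting, per band and channel, the mean DE of the
pre-stimulus windows, mapped onto the electrode grid, and stacked into 4D
model inputs of shape (grid_h, grid_w, bands, 2T) where 2T consecutive
0.5-s slices form one sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .io_layouts import ElectrodeLayout
from .preprocess import SegmentSet

__all__ = [
    "DEFeatures",
    "Sample4D",
    "differential_entropy",
    "spectral_de",
    "de_features",
    "baseline_correct",
    "split_baseline",
    "map_channels_to_grid",
    "gather_from_grid",
    "assemble_4d",
]

_HALF_LOG_2PIE = 0.5 * np.log(2.0 * np.pi * np.e)


@dataclass
class DEFeatures:
    """Per-trial DE values: ``values`` is (segments, bands, channels), nats."""

    values: np.ndarray
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("DEFeatures must be (segments, bands, channels)")


@dataclass
class Sample4D:
    """One model input: ``tensor`` is (grid_h, grid_w, bands, 2T)."""

    tensor: np.ndarray
    label: int
    trial_id: int = 0
    slice_range: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 4:
            raise ValueError("Sample4D tensor must be rank 4: h x w x bands x 2T")


def _sigma2(segment: np.ndarray, zero_mean: bool, axis: int = -1) -> np.ndarray:
    x = np.asarray(segment, dtype=np.float64)
    if x.shape[axis] < 2:
        raise ValueError("segments need at least 2 samples")
    if not zero_mean:
        x = x - x.mean(axis=axis, keepdims=True)
    return np.mean(x * x, axis=axis)


def differential_entropy(segment: np.ndarray, zero_mean: bool = False, axis: int = -1):
    """DE of a segment in nats: ``0.5*ln(2*pi*e*sigma^2)``.

    The variance estimate is the mean square ``sum(x_i^2)/N``.  Band-passed
    EEG is zero-mean by construction; with ``zero_mean=False`` (default) the
    segment mean is subtracted first, which makes the feature invariant to
    DC offsets, while ``zero_mean=True`` uses the raw energy.  Zero variance
    yields ``-inf`` with a warning.
    """
    s2 = _sigma2(segment, zero_mean, axis)
    with np.errstate(divide="ignore"):
        out = _HALF_LOG_2PIE + 0.5 * np.log(s2)
    if np.any(s2 == 0.0):
        warnings.warn("zero-variance segment: differential entropy is -inf")
    return out if out.ndim else float(out)


def spectral_de(segment: np.ndarray, zero_mean: bool = False, axis: int = -1):
    """DE via the discrete Fourier energy spectrum (Parseval route).

    ``0.5*log(P) + 0.5*log(2*pi*e/N)`` with ``P = sum_k |X_k|^2 / N``.
    Numerically equal to :func:`differential_entropy` for any segment.
    """
    x = np.asarray(segment, dtype=np.float64)
    n = x.shape[axis]
    if n < 2:
        raise ValueError("segments need at least 2 samples")
    if not zero_mean:
        x = x - x.mean(axis=axis, keepdims=True)
    p = np.sum(np.abs(np.fft.fft(x, axis=axis)) ** 2, axis=axis) / n
    with np.errstate(divide="ignore"):
        out = 0.5 * np.log(p) + 0.5 * np.log(2.0 * np.pi * np.e / n)
    if np.any(p == 0.0):
        warnings.warn("zero-energy segment: differential entropy is -inf")
    return out if out.ndim else float(out)


def de_features(segments: SegmentSet, zero_mean: bool = False) -> DEFeatures:
    """DE of every (segment, band, channel) window of a segmented trial."""
    vals = differential_entropy(segments.data, zero_mean=zero_mean, axis=-1)
    return DEFeatures(values=vals)


def split_baseline(de: DEFeatures, n_baseline: int) -> Tuple[np.ndarray, DEFeatures]:
    """Split leading baseline windows from the emotional portion.

    For a 3-s baseline at 0.5-s windows ``n_baseline`` is 6.
    """
    if n_baseline < 1:
        raise ValueError("need at least one baseline window")
    if de.values.shape[0] <= n_baseline:
        raise ValueError("no emotional segments left after the baseline prefix")
    return de.values[:n_baseline], DEFeatures(values=de.values[n_baseline:])


def baseline_correct(features, base_features) -> np.ndarray | float:
    """Subtract the mean pre-stimulus feature value.

    ``EEG_removed_t = feature_t - mean(base_feature_1..k)``, applied
    elementwise per band and channel.  ``base_features`` is a non-empty list
    of baseline feature frames (or scalars).
    """
    base = np.asarray(base_features, dtype=np.float64)
    if base.size == 0:
        raise ValueError("baseline feature list is empty")
    corrected = np.asarray(features, dtype=np.float64) - base.mean(axis=0)
    return corrected if corrected.ndim else float(corrected)


def map_channels_to_grid(values: Sequence[float], layout: ElectrodeLayout) -> np.ndarray:
    """Scatter per-channel values onto the scalp grid; empty cells stay 0."""
    v = np.asarray(values, dtype=np.float64)
    if v.shape[-1] != layout.n_channels:
        raise ValueError(
            f"got {v.shape[-1]} values for a {layout.n_channels}-channel layout"
        )
    rows, cols = layout.rows_cols()
    grid = np.zeros(v.shape[:-1] + (layout.grid_h, layout.grid_w))
    grid[..., rows, cols] = v
    return grid


def gather_from_grid(grid: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Inverse of :func:`map_channels_to_grid` (layout channel order)."""
    rows, cols = layout.rows_cols()
    return np.asarray(grid, dtype=np.float64)[..., rows, cols]


def assemble_4d(
    de: DEFeatures,
    layout: ElectrodeLayout,
    two_t: int = 6,
    label: int = 0,
    trial_id: int = 0,
) -> List[Sample4D]:
    """Stack 2T consecutive feature slices into 4D samples.

    Consecutive non-overlapping blocks of ``two_t`` segment slices form one
    sample each; a trailing remainder is dropped, so a trial with l segments
    yields floor(l / 2T) samples.  Every slice is the band-stacked grid map
    of that segment's DE values; grid cells without an electrode are zero in
    every band and slice.
    """
    if two_t < 1:
        raise ValueError("2T must be >= 1")
    l, n_bands, n_ch = de.values.shape
    if two_t > l:
        raise ValueError(f"2T={two_t} exceeds the {l} available segments")
    if n_ch != layout.n_channels:
        raise ValueError(
            f"features have {n_ch} channels but layout has {layout.n_channels}"
        )
    # (l, bands, h, w)
    grids = map_channels_to_grid(de.values, layout)
    samples = []
    for k in range(l // two_t):
        block = grids[k * two_t : (k + 1) * two_t]  # (2T, bands, h, w)
        tensor = block.transpose(2, 3, 1, 0)  # (h, w, bands, 2T)
        samples.append(
            Sample4D(
                tensor=np.ascontiguousarray(tensor),
                label=label,
                trial_id=trial_id,
                slice_range=(k * two_t, (k + 1) * two_t),
            )
        )
    return samples
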