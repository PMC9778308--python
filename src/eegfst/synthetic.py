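"""Synthetic EEG archives with controllable class-dependent band power.

The generator emulates the preprocessed DEAP trial geometry exactly
(40 x 40 x 8064 at 128 Hz: 63-s trials whose first 3 s are pre-stimulus
baseline; EEG on the first 32 channels) so that every downstream stage of
the pipeline can be exercised without the licensed recordings.

Each EEG channel is a sum of five independent band-limited Gaussian
processes (one per classical rhythm) plus a 1/f pink-noise background.
Emotion classes differ only through variance multipliers rho applied to
designated (band, channel) pairs during the emotional portion of the
trial; the baseline prefix always uses the base variances.  Because
differential entropy of a Gaussian band is 0.5*ln(2*pi*e*sigma^2), a
multiplier rho shifts the baseline-corrected DE of affected cells by about
0.5*ln(rho) nats, which is the recoverable ground-truth effect.

Band-limited noise is produced by shaping white Gaussian noise in the
frequency domain (zeroing out-of-band Fourier coefficients and rescaling),
deliberately independent of the analysis-side Butterworth filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .io_layouts import DEAP_N_EEG, RawTrial, DEAP_CHANNELS, write_deap_archive
from .preprocess import BAND_NAMES, DEFAULT_BANDS

__all__ = [
    "ClassEffect",
    "SynthSpec",
    "band_limited_noise",
    "pink_noise",
    "generate_trials",
    "generate_archive",
]

#: Root seed for the default generator configuration.
DEFAULT_SEED = 20221830

#: Base variance of each rhythm component (unitless uV^2-scale); a gentle
#: 1/f-like decline across bands, as in resting EEG spectra.
DEFAULT_BASE_VARIANCES: Tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2)

_BAND_INDEX: Dict[str, int] = {name: i for i, name in enumerate(BAND_NAMES)}


@dataclass(frozen=True)
class ClassEffect:
    """Variance multiplier ``rho`` on one band for a channel subset of a class."""

    class_label: int
    band: str
    channels: Tuple[int, ...]
    rho: float

    def __post_init__(self) -> None:
        if self.band not in _BAND_INDEX:
            raise ValueError(f"unknown band {self.band!r}; expected one of {BAND_NAMES}")
        if self.rho < 0:
            raise ValueError("variance multiplier rho must be >= 0")
        if self.class_label < 0:
            raise ValueError("class labels are non-negative integers")


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic archive (shapes, noise, effects)."""

    n_trials: int = 40
    n_channels: int = 40
    fs: float = 128.0
    trial_s: float = 63.0
    baseline_s: float = 3.0
    band_edges: Tuple[Tuple[float, float], ...] = DEFAULT_BANDS
    base_variances: Tuple[float, ...] = DEFAULT_BASE_VARIANCES
    class_effects: Tuple[ClassEffect, ...] = ()
    pink_amplitude: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if abs(self.trial_s * self.fs - round(self.trial_s * self.fs)) > 1e-9:
            raise ValueError("trial_s * fs must be an integer sample count")
        if len(self.base_variances) != len(self.band_edges):
            raise ValueError("one base variance per band is required")
        if any(v < 0 for v in self.base_variances):
            raise ValueError("band variances must be >= 0")
        if self.pink_amplitude < 0:
            raise ValueError("pink-noise amplitude must be >= 0")
        if self.n_channels < 1 or self.n_trials < 1:
            raise ValueError("n_trials and n_channels must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_s * self.fs))

    @property
    def n_classes(self) -> int:
        if not self.class_effects:
            return 2
        return max(e.class_label for e in self.class_effects) + 1

    @staticmethod
    def two_class(
        n_per_class: int = 20,
        rho: float = 6.0,
        bands: Sequence[str] = ("beta", "gamma"),
        channels: Sequence[int] = (2, 3, 6, 7, 19, 22, 24, 28),
        seed: int = DEFAULT_SEED,
    ) -> "SynthSpec":
        """Two balanced classes; class 1 carries ``rho`` on the given bands.

        The default affected channels sample frontal, central and parietal
        sites of the 32-channel montage.
        """
        effects = tuple(
            ClassEffect(class_label=1, band=b, channels=tuple(channels), rho=rho)
            for b in bands
        )
        return SynthSpec(n_trials=2 * n_per_class, class_effects=effects, seed=seed)


def band_limited_noise(
    band_edges: Tuple[float, float],
    fs: float,
    n: int,
    variance: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Gaussian noise whose spectral support is exactly ``[low, high]`` Hz.

    White Gaussian noise is transformed to the frequency domain, coefficients
    outside the band are zeroed, and the inverse transform is rescaled to the
    target sample variance (exact; zero mean by construction since the DC
    coefficient is removed).
    """
    lo, hi = float(band_edges[0]), float(band_edges[1])
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"band edges must satisfy 0 < low < high < fs/2, got ({lo}, {hi})")
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    if variance == 0.0:
        return np.zeros(n)
    sd = x.std()
    if sd == 0.0:  # band so narrow no bin survived
        raise ValueError(f"band ({lo}, {hi}) Hz contains no DFT bin at n={n}, fs={fs}")
    return x * (np.sqrt(variance) / sd)


def pink_noise(n: int, fs: float, amplitude: float, rng: np.random.Generator,
               f_min: float = 0.5) -> np.ndarray:
    """1/f-amplitude Gaussian background, rescaled to std ``amplitude``."""
    if amplitude == 0.0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs >= f_min
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * shaping, n=n)
    return x * (amplitude / x.std())


def _trial_classes(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Balanced random class assignment over trials."""
    k = spec.n_classes
    base = np.arange(spec.n_trials) % k
    return rng.permutation(base)


def _effect_table(spec: SynthSpec) -> Dict[Tuple[int, int, int], float]:
    """(class, band, channel) -> cumulative variance multiplier."""
    table: Dict[Tuple[int, int, int], float] = {}
    for eff in spec.class_effects:
        b = _BAND_INDEX[eff.band]
        for ch in eff.channels:
            if not (0 <= ch < DEAP_N_EEG):
                raise ValueError(f"effect channel {ch} outside the EEG range 0..{DEAP_N_EEG - 1}")
            key = (eff.class_label, b, ch)
            table[key] = table.get(key, 1.0) * eff.rho
    return table


def generate_trials(spec: SynthSpec) -> Tuple[List[RawTrial], np.ndarray]:
    """Generate the trials of an archive and their ground-truth classes.

    Deterministic in ``spec.seed``: identical specs yield identical samples.
    """
    rng = np.random.default_rng(spec.seed)
    classes = _trial_classes(spec, rng)
    effects = _effect_table(spec)
    n = spec.n_samples
    n_base = int(round(spec.baseline_s * spec.fs))
    n_eeg = min(DEAP_N_EEG, spec.n_channels)
    trials: List[RawTrial] = []
    for t in range(spec.n_trials):
        cls = int(classes[t])
        data = np.zeros((spec.n_channels, n))
        for ch in range(n_eeg):
            x = pink_noise(n, spec.fs, spec.pink_amplitude, rng)
            for b, (edges, base_var) in enumerate(zip(spec.band_edges, spec.base_variances)):
                comp = band_limited_noise(edges, spec.fs, n, 1.0, rng)
                rho = effects.get((cls, b, ch), 1.0)
                x[:n_base] += comp[:n_base] * np.sqrt(base_var)
                x[n_base:] += comp[n_base:] * np.sqrt(base_var * rho)
            data[ch] = x
        # peripheral channels: unit-variance white noise, DEAP-layout filler
        for ch in range(n_eeg, spec.n_channels):
            data[ch] = rng.standard_normal(n)
        names = tuple(DEAP_CHANNELS[:n_eeg]) + tuple(
            f"periph{j}" for j in range(spec.n_channels - n_eeg)
        )
        trials.append(
            RawTrial(
                samples=data,
                fs=spec.fs,
                channel_names=names,
                baseline_s=spec.baseline_s,
                labels=_ratings_for_class(cls),
                trial_id=t,
            )
        )
    return trials, classes


def _ratings_for_class(cls: int) -> Tuple[float, float, float, float]:
    """DEAP-style 1-9 ratings consistent with the generating class.

    Class 1 (high) maps to valence/arousal 8.0, class 0 (low) to 2.0, so the
    default binarization threshold of 5 recovers the class; further classes
    are recorded in the dominance slot for bookkeeping.
    """
    hi_lo = 8.0 if cls >= 1 else 2.0
    return (hi_lo, hi_lo, float(cls), 5.0)


def generate_archive(spec: SynthSpec, path: str | None = None):
    """Generate a DEAP-shaped archive; optionally write it to HDF5.

    Returns ``(trials, classes)``; when ``path`` is given, also writes the
    full (n_trials x n_channels x n_samples) ``/data`` and (n_trials x 4)
    ``/labels`` datasets.
    """
    trials, classes = generate_trials(spec)
    if path is not None:
        data = np.stack([t.samples for t in trials])
        labels = np.array([t.labels for t in trials], dtype=np.float64)
        write_deap_archive(path, data, labels)
    return trials, classes
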