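"""Trial archives, electrode layouts and the intermediate feature store.

Conventions used throughout the package
---------------------------------------

* A *trial archive* is an HDF5 file with two datasets: ``/data`` of shape
  ``(videos, channels, samples)`` (float32) and ``/labels`` of shape
  ``(videos, 4)`` holding valence, arousal, dominance and liking ratings on
  the 1-9 scale.  This mirrors the preprocessed per-subject layout of the
  DEAP benchmark (40 videos x 40 channels x 8064 samples at 128 Hz; the
  first 32 channels are EEG, the remainder peripheral physiology).
* Electrode layouts are plain CSV files: a ``#grid=H,W`` header followed by
  ``channel_name,row,col`` rows.  Coordinates are 0-based and row-major with
  row 0 at the frontal (nasion) edge of the scalp.
* The feature store persists differential-entropy features as an HDF5
  dataset ``/de`` shaped ``(trials, segments, bands, channels)`` with the
  band edges, window length, layout id and baseline-correction flag stored
  as attributes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np

__all__ = [
    "RawTrial",
    "ElectrodeLayout",
    "FeatureStore",
    "FormatError",
    "DEAP_SHAPE",
    "DEAP_N_EEG",
    "DEAP_FS",
    "DEAP_BASELINE_S",
    "DEAP_CHANNELS",
    "SEED_LABEL_NAMES",
    "read_deap_archive",
    "write_deap_archive",
    "read_seed_archive",
    "write_seed_archive",
    "binarize_deap_labels",
    "read_layout",
    "write_layout",
    "bundled_layout",
    "read_feature_store",
    "write_feature_store",
]


class FormatError(ValueError):
    """An on-disk archive or layout does not match its declared format."""


#: DEAP preprocessed per-subject shapes: videos x channels x samples.
DEAP_SHAPE = (40, 40, 8064)
#: Only the first 32 of the 40 recorded channels are EEG.
DEAP_N_EEG = 32
#: Sampling rate of the preprocessed recordings, Hz.
DEAP_FS = 128.0
#: Pre-stimulus baseline prefix of every trial, seconds.
DEAP_BASELINE_S = 3.0

#: Geneva ordering of the 32 DEAP EEG channels.
DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Three-class label encoding for SEED-like archives; the index is the class.
SEED_LABEL_NAMES = ("negative", "neutral", "positive")


@dataclass
class RawTrial:
    """One trial's multichannel samples plus recording metadata.

    ``samples`` is ``(channels, time_points)``; ``labels`` is the ordered
    rating list (valence, arousal, dominance, liking for DEAP-style trials,
    or a single class index for SEED-style trials).  The first
    ``baseline_s`` seconds of every channel are pre-stimulus baseline.
    """

    samples: np.ndarray
    fs: float
    channel_names: Tuple[str, ...]
    baseline_s: float
    labels: Tuple[float, ...]
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a (channels, time) matrix with >=1 channel")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.samples.shape[0]} channels"
            )
        if self.samples.shape[1] < self.fs * self.baseline_s:
            raise ValueError("trial shorter than its declared baseline prefix")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass(frozen=True)
class ElectrodeLayout:
    """Assignment of channel names to cells of an ``grid_h x grid_w`` scalp grid.

    Cells that carry no electrode stay structurally zero in every mapped
    feature matrix.
    """

    grid_h: int
    grid_w: int
    assignment: Dict[str, Tuple[int, int]]
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.grid_h < 1 or self.grid_w < 1:
            raise ValueError("grid dimensions must be positive")
        if len(self.assignment) > self.grid_h * self.grid_w:
            raise ValueError("more channels than grid cells")
        seen: Dict[Tuple[int, int], str] = {}
        for ch, (r, c) in self.assignment.items():
            if not (0 <= r < self.grid_h and 0 <= c < self.grid_w):
                raise ValueError(f"channel {ch!r} cell ({r},{c}) outside {self.grid_h}x{self.grid_w} grid")
            if (r, c) in seen:
                raise ValueError(f"channels {seen[r, c]!r} and {ch!r} share cell ({r},{c})")
            seen[r, c] = ch

    @property
    def channels(self) -> Tuple[str, ...]:
        return tuple(self.assignment)

    @property
    def n_channels(self) -> int:
        return len(self.assignment)

    def rows_cols(self, channel_order: Sequence[str] | None = None) -> Tuple[np.ndarray, np.ndarray]:
        """Row/col index arrays for ``channel_order`` (layout order by default)."""
        order = tuple(channel_order) if channel_order is not None else self.channels
        missing = [ch for ch in order if ch not in self.assignment]
        if missing:
            raise ValueError(f"channels not in layout: {missing}")
        rc = np.array([self.assignment[ch] for ch in order], dtype=int)
        return rc[:, 0], rc[:, 1]


@dataclass
class FeatureStore:
    """Differential-entropy features for a set of trials.

    ``de`` is ``(trials, segments, bands, channels)``; metadata records how
    the features were produced so downstream stages can validate against it.
    """

    de: np.ndarray
    band_edges: Tuple[Tuple[float, float], ...]
    window_s: float
    layout_id: str
    baseline_corrected: bool
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.de = np.asarray(self.de, dtype=np.float64)
        if self.de.ndim != 4:
            raise ValueError("de must be rank-4: trials x segments x bands x channels")
        if self.de.shape[2] != len(self.band_edges):
            raise ValueError(
                f"band axis has length {self.de.shape[2]} but {len(self.band_edges)} band edges given"
            )
        if not np.all(np.isfinite(self.de)):
            raise ValueError("feature store contains non-finite values")


# ---------------------------------------------------------------------------
# trial archives
# ---------------------------------------------------------------------------

def read_deap_archive(path: str | Path) -> List[RawTrial]:
    """Read a DEAP-layout trial archive into per-trial objects.

    Only the 32 EEG channels are retained; the sampling rate (128 Hz) and
    the 3-s baseline prefix are fixed by the format.
    """
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError("archive is missing the /data dataset")
        if "labels" not in f:
            raise FormatError("archive is missing the /labels dataset")
        data = np.asarray(f["data"], dtype=np.float64)
        labels = np.asarray(f["labels"], dtype=np.float64)
    if data.shape != DEAP_SHAPE:
        for axis, (got, want) in enumerate(zip(data.shape, DEAP_SHAPE)):
            if got != want:
                axis_name = ("video", "channel", "sample")[axis]
                raise FormatError(
                    f"/data {axis_name} axis has length {got}, expected {want} "
                    f"(full expected shape {DEAP_SHAPE})"
                )
    if labels.shape != (DEAP_SHAPE[0], 4):
        raise FormatError(
            f"/labels has shape {labels.shape}, expected {(DEAP_SHAPE[0], 4)}"
        )
    trials = []
    for i in range(DEAP_SHAPE[0]):
        trials.append(
            RawTrial(
                samples=data[i, :DEAP_N_EEG],
                fs=DEAP_FS,
                channel_names=DEAP_CHANNELS,
                baseline_s=DEAP_BASELINE_S,
                labels=tuple(labels[i]),
                trial_id=i,
            )
        )
    return trials


def read_deap_pickle(path: str | Path) -> List[RawTrial]:
    """Optional adapter for the original pickled per-subject DEAP files.

    The upstream distribution ships ``sXX.dat`` files: a Python-2 pickle of
    ``{"data": (40, 40, 8064), "labels": (40, 4)}``.  Provided for users who
    hold the licensed download; everything else in the package uses the
    HDF5 dialect.
    """
    import pickle

    with open(path, "rb") as f:
        payload = pickle.load(f, encoding="latin1")
    data = np.asarray(payload["data"], dtype=np.float64)
    labels = np.asarray(payload["labels"], dtype=np.float64)
    tmp_trials = []
    if data.shape != DEAP_SHAPE or labels.shape != (DEAP_SHAPE[0], 4):
        raise FormatError(
            f"pickle payload has shapes {data.shape}/{labels.shape}, "
            f"expected {DEAP_SHAPE}/{(DEAP_SHAPE[0], 4)}"
        )
    for i in range(DEAP_SHAPE[0]):
        tmp_trials.append(
            RawTrial(
                samples=data[i, :DEAP_N_EEG],
                fs=DEAP_FS,
                channel_names=DEAP_CHANNELS,
                baseline_s=DEAP_BASELINE_S,
                labels=tuple(labels[i]),
                trial_id=i,
            )
        )
    return tmp_trials


def write_deap_archive(path: str | Path, data: np.ndarray, labels: np.ndarray) -> None:
    """Write a DEAP-layout archive (``/data`` 40x40x8064, ``/labels`` 40x4)."""
    data = np.asarray(data, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.float32)
    if data.ndim != 3:
        raise FormatError(f"data must be videos x channels x samples, got shape {data.shape}")
    if labels.shape != (data.shape[0], 4):
        raise FormatError(f"labels must be shaped {(data.shape[0], 4)}, got {labels.shape}")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("labels", data=labels)


def read_seed_archive(path: str | Path) -> List[RawTrial]:
    """Read a SEED-like session archive.

    Dialect: one HDF5 group per trial (``/trial_000`` ...), each with a
    ``data`` dataset shaped (62, time) and an integer ``label`` attribute in
    {0: negative, 1: neutral, 2: positive}; file attributes ``fs`` and
    ``channels``.
    """
    trials = []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs.get("fs", 200.0))
        channels = tuple(str(c) for c in f.attrs["channels"])
        names = sorted(k for k in f.keys() if k.startswith("trial_"))
        if not names:
            raise FormatError("archive contains no trial_* groups")
        for i, key in enumerate(names):
            g = f[key]
            samples = np.asarray(g["data"], dtype=np.float64)
            if samples.shape[0] != len(channels):
                raise FormatError(
                    f"{key}: channel axis has length {samples.shape[0]}, "
                    f"expected {len(channels)}"
                )
            label = int(g.attrs["label"])
            if label not in (0, 1, 2):
                raise FormatError(f"{key}: label {label} not in {{0,1,2}}")
            trials.append(
                RawTrial(
                    samples=samples,
                    fs=fs,
                    channel_names=channels,
                    baseline_s=float(g.attrs.get("baseline_s", 0.0)),
                    labels=(float(label),),
                    trial_id=i,
                )
            )
    return trials


def write_seed_archive(
    path: str | Path,
    trials: Sequence[np.ndarray],
    labels: Sequence[int],
    channels: Sequence[str],
    fs: float = 200.0,
    baseline_s: float = 0.0,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(fs)
        f.attrs["channels"] = [str(c) for c in channels]
        for i, (samples, label) in enumerate(zip(trials, labels)):
            g = f.create_group(f"trial_{i:03d}")
            g.create_dataset("data", data=np.asarray(samples, dtype=np.float32))
            g.attrs["label"] = int(label)
            g.attrs["baseline_s"] = float(baseline_s)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

_DEAP_DIMS = {"valence": 0, "arousal": 1, "dominance": 2, "liking": 3}


def binarize_deap_labels(
    labels: Sequence[float], dimension: str = "valence", threshold: float = 5.0
) -> int:
    """Binarize a 1-9 affective rating into low (0) / high (1).

    The split is strict: ratings above ``threshold`` are high, ratings at or
    below it are low.
    """
    if dimension not in _DEAP_DIMS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {sorted(_DEAP_DIMS)}")
    rating = float(labels[_DEAP_DIMS[dimension]])
    if not (1.0 <= rating <= 9.0):
        raise ValueError(f"{dimension} rating {rating} outside the 1-9 scale")
    return 1 if rating > threshold else 0


# ---------------------------------------------------------------------------
# electrode layouts
# ---------------------------------------------------------------------------

def read_layout(path: str | Path, name: str | None = None) -> ElectrodeLayout:
    """Parse an electrode layout CSV (``#grid=H,W`` header, then name,row,col)."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#grid="):
        raise FormatError("layout file must start with a '#grid=H,W' header")
    try:
        h, w = (int(x) for x in lines[0][len("#grid="):].split(","))
    except ValueError as exc:
        raise FormatError(f"malformed grid header {lines[0]!r}") from exc
    assignment: Dict[str, Tuple[int, int]] = {}
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 3:
            raise FormatError(f"malformed layout row {ln!r}")
        ch, r, c = parts[0], int(parts[1]), int(parts[2])
        if ch in assignment:
            raise ValueError(f"channel {ch!r} listed twice")
        assignment[ch] = (r, c)
    return ElectrodeLayout(h, w, assignment, name=name or path.stem)


def write_layout(path: str | Path, layout: ElectrodeLayout) -> None:
    rows = [f"#grid={layout.grid_h},{layout.grid_w}"]
    rows += [f"{ch},{r},{c}" for ch, (r, c) in layout.assignment.items()]
    Path(path).write_text("\n".join(rows) + "\n")


_BUNDLED = {
    "deap32_8x9": "deap32_8x9.csv",
    "seed62_8x9": "seed62_8x9.csv",
    "seed62_19x19": "seed62_19x19.csv",
}


def bundled_layout(name: str = "deap32_8x9") -> ElectrodeLayout:
    """One of the layouts shipped with the package.

    ``deap32_8x9``   32 DEAP channels on the compact 8x9 scalp grid
    ``seed62_8x9``   62 SEED channels on the compact 8x9 grid
    ``seed62_19x19`` 62 SEED channels spread on the sparse 19x19 grid
    """
    if name not in _BUNDLED:
        raise ValueError(f"unknown bundled layout {name!r}; available: {sorted(_BUNDLED)}")
    ref = importlib.resources.files("eegfst.layouts") / _BUNDLED[name]
    with importlib.resources.as_file(ref) as path:
        return read_layout(path, name=name)


# ---------------------------------------------------------------------------
# feature store
# ---------------------------------------------------------------------------

def write_feature_store(path: str | Path, store: FeatureStore) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("de", data=store.de.astype(np.float32))
        d.attrs["band_edges"] = np.asarray(store.band_edges, dtype=np.float64)
        d.attrs["window_s"] = store.window_s
        d.attrs["layout_id"] = store.layout_id
        d.attrs["baseline_corrected"] = bool(store.baseline_corrected)
        f.create_dataset("labels", data=np.asarray(store.labels, dtype=np.float64))


def read_feature_store(path: str | Path) -> FeatureStore:
    with h5py.File(path, "r") as f:
        if "de" not in f:
            raise FormatError("feature store is missing the /de dataset")
        d = f["de"]
        edges = tuple(tuple(e) for e in np.asarray(d.attrs["band_edges"]))
        return FeatureStore(
            de=np.asarray(d, dtype=np.float64),
            band_edges=edges,
            window_s=float(d.attrs["window_s"]),
            layout_id=str(d.attrs["layout_id"]),
            baseline_corrected=bool(d.attrs["baseline_corrected"]),
            labels=np.asarray(f["labels"], dtype=np.float64) if "labels" in f else np.zeros(0),
        )
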