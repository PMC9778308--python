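"""Trial-level k-fold cross-validated training, evaluation and metrics.

Folds are formed over *trials* (videos), not over samples: every 4D sample
derived from a trial follows that trial into its fold, so no segment of a
test trial ever contributes to training (no leakage).  Each fold trains a
fresh model; the headline numbers are the mean and standard deviation of
the per-fold accuracies, alongside a pooled confusion matrix and per-class
precision/recall/F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .features import Sample4D, assemble_4d, baseline_correct, de_features, split_baseline
from .io_layouts import ElectrodeLayout, RawTrial
from .model import CNNConfig, FSTception
from .nn import Adam, softmax_cross_entropy
from .preprocess import DEFAULT_BANDS, apply_filter_bank, design_filter_bank, segment

__all__ = [
    "TrainConfig",
    "EvalReport",
    "make_folds",
    "trials_to_samples",
    "train_model",
    "run_cv",
    "compute_metrics",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the defaults are the full-scale recipe
    (Adam, learning rate 0.003, batch 120, 100 epochs, 5 folds)."""

    lr: float = 0.003
    batch_size: int = 120
    epochs: int = 100
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("need at least 1 epoch")


@dataclass
class EvalReport:
    """Cross-validation outcome.

    ``std_acc`` is the sample standard deviation (ddof=1) of the per-fold
    accuracies.  ``confusion`` pools predictions over all evaluated folds,
    rows = true class, columns = predicted.  Per-class accuracy is
    one-vs-rest; precision/recall/F1 are NaN for classes absent from both
    the true and predicted labels.
    """

    fold_accuracies: List[float]
    confusion: np.ndarray
    class_names: Tuple[str, ...]
    per_class: Dict[str, Dict[str, float]]
    skipped_folds: List[int] = field(default_factory=list)
    fold_losses: List[List[float]] = field(default_factory=list)

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_acc(self) -> float:
        if len(self.fold_accuracies) < 2:
            return 0.0
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else float("nan")

    def to_dict(self) -> dict:
        def _clean(v: float):  # undefined metrics serialize as null, not NaN
            return None if isinstance(v, float) and np.isnan(v) else v

        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_acc": self.mean_acc,
            "std_acc": self.std_acc,
            "accuracy": _clean(self.accuracy),
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
            "per_class": {
                k: {m: _clean(x) for m, x in d.items()} for k, d in self.per_class.items()
            },
            "skipped_folds": self.skipped_folds,
        }


def make_folds(
    trial_ids: Sequence[int], k: int, seed: int = 0
) -> List[np.ndarray]:
    """Randomly partition trial ids into k test groups of near-equal size."""
    ids = np.asarray(list(trial_ids))
    if k > ids.size:
        raise ValueError(f"cannot make {k} folds from {ids.size} trials")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    return [np.sort(g) for g in np.array_split(perm, k)]


def trials_to_samples(
    trials: Sequence[RawTrial],
    labels: Sequence[int],
    layout: ElectrodeLayout,
    window_s: float = 0.5,
    two_t: int = 6,
    band_edges=DEFAULT_BANDS,
    baseline_corrected: bool = True,
) -> List[Sample4D]:
    """Full feature pipeline: bands -> segments -> DE -> correction -> 4D.

    Trials are segmented from t=0 so the pre-stimulus windows are available
    for baseline correction; the emotional-portion features are corrected
    per band and channel, then blocked into 2T-slice samples that inherit
    the trial label.
    """
    if len(trials) != len(labels):
        raise ValueError("one label per trial required")
    banks = {}
    samples: List[Sample4D] = []
    for trial, label in zip(trials, labels):
        # keep only the layout's channels, in layout order (drops e.g. the
        # peripheral-physiology channels of DEAP-shaped archives)
        name_to_row = {ch: i for i, ch in enumerate(trial.channel_names)}
        missing = [ch for ch in layout.channels if ch not in name_to_row]
        if missing:
            raise ValueError(f"trial {trial.trial_id} lacks layout channels {missing}")
        sel = [name_to_row[ch] for ch in layout.channels]
        trial = RawTrial(
            samples=trial.samples[sel],
            fs=trial.fs,
            channel_names=layout.channels,
            baseline_s=trial.baseline_s,
            labels=trial.labels,
            trial_id=trial.trial_id,
        )
        if trial.fs not in banks:
            banks[trial.fs] = design_filter_bank(trial.fs, band_edges)
        bands = apply_filter_bank(trial, banks[trial.fs])
        segs = segment(bands, window_s=window_s, skip_s=0.0)
        de = de_features(segs)
        n_base = int(round(trial.baseline_s / window_s))
        if baseline_corrected and n_base > 0:
            base, emo = split_baseline(de, n_base)
            emo.values = baseline_correct(emo.values, base)
            emo.baseline_corrected = True
        else:
            emo = de
        samples.extend(
            assemble_4d(emo, layout, two_t=two_t, label=int(label), trial_id=trial.trial_id)
        )
    return samples


def _stack(samples: Sequence[Sample4D]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.stack([s.tensor for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.intp)
    tid = np.array([s.trial_id for s in samples])
    return x, y, tid


def train_model(
    model: FSTception,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> List[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss."""
    opt = Adam(model.parameters(), lr=cfg.lr)
    model.train()
    losses = []
    n = len(x)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            opt.zero_grad()
            loss = softmax_cross_entropy(model.forward(x[idx]), y[idx])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    model.eval()
    return losses


def run_cv(
    trials: Sequence[RawTrial],
    labels: Sequence[int],
    layout: ElectrodeLayout,
    cnn_cfg: Optional[CNNConfig] = None,
    train_cfg: TrainConfig = TrainConfig(),
    hidden: int = 128,
    two_t: int = 6,
    variant: str = "as_printed",
    shuffle_labels: bool = False,
) -> EvalReport:
    """k-fold cross-validation at the trial level.

    A fresh model is trained per fold on the samples of the training
    trials and evaluated on the samples of the held-out trials.  With
    ``shuffle_labels`` the trial labels are randomly permuted first (the
    chance-level control).  Folds whose training split contains a single
    class are skipped with a warning and reported.
    """
    labels = np.asarray([int(l) for l in labels])
    n_classes = int(labels.max()) + 1
    ss = np.random.SeedSequence(train_cfg.seed)
    fold_seed, shuffle_seed, *fold_ss = ss.spawn(2 + train_cfg.k_folds)
    if shuffle_labels:
        labels = np.random.default_rng(shuffle_seed).permutation(labels)
    if cnn_cfg is None:
        cnn_cfg = CNNConfig.reduced(layout.grid_h, layout.grid_w, len(DEFAULT_BANDS))
    samples = trials_to_samples(trials, labels, layout, two_t=two_t)
    x, y, tid = _stack(samples)
    trial_ids = [t.trial_id for t in trials]
    folds = make_folds(trial_ids, train_cfg.k_folds, seed=fold_seed.generate_state(1)[0])

    fold_accs: List[float] = []
    fold_losses: List[List[float]] = []
    skipped: List[int] = []
    y_true_all: List[np.ndarray] = []
    y_pred_all: List[np.ndarray] = []
    for f, test_ids in enumerate(folds):
        test_mask = np.isin(tid, test_ids)
        x_tr, y_tr = x[~test_mask], y[~test_mask]
        x_te, y_te = x[test_mask], y[test_mask]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {f}: training split has a single class; skipped")
            skipped.append(f)
            continue
        child = fold_ss[f]
        model_seed = int(child.generate_state(1)[0] % (2**31))
        model = FSTception(cnn=cnn_cfg, hidden=hidden, n_classes=n_classes,
                           variant=variant, seed=model_seed)
        rng = np.random.default_rng(child)
        losses = train_model(model, x_tr, y_tr, train_cfg, rng)
        pred = model.predict(x_te)
        fold_accs.append(float((pred == y_te).mean()))
        fold_losses.append(losses)
        y_true_all.append(y_te)
        y_pred_all.append(pred)

    if not fold_accs:
        raise ValueError("all folds were skipped; cannot evaluate")
    class_names = tuple(str(c) for c in range(n_classes))
    report = compute_metrics(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), class_names
    )
    report.fold_accuracies = fold_accs
    report.fold_losses = fold_losses
    report.skipped_folds = skipped
    return report


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], class_names: Sequence[str]
) -> EvalReport:
    """Confusion matrix and per-class precision/recall/F1/accuracy.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    per-class accuracy is one-vs-rest; overall accuracy is the trace of the
    confusion matrix over its total.  A class absent from both label lists
    gets NaN markers.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label lists must have equal length")
    idx = np.arange(len(class_names))
    cm = _sk_confusion(y_true, y_pred, labels=idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = _sk_prfs(y_true, y_pred, labels=idx, zero_division=np.nan)
    total = cm.sum()
    per_class: Dict[str, Dict[str, float]] = {}
    for i, name in enumerate(class_names):
        present = cm[i].sum() + cm[:, i].sum() > 0
        tp = cm[i, i]
        tn = total - cm[i].sum() - cm[:, i].sum() + tp
        per_class[str(name)] = {
            "accuracy": float((tp + tn) / total) if present and total else float("nan"),
            "precision": float(prec[i]) if present else float("nan"),
            "recall": float(rec[i]) if present else float("nan"),
            "f1": float(f1[i]) if present else float("nan"),
        }
    acc_list = [float(np.trace(cm) / total)] if total else []
    return EvalReport(
        fold_accuracies=acc_list,
        confusion=cm,
        class_names=tuple(str(c) for c in class_names),
        per_class=per_class,
    )
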