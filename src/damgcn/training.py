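"""Training loop and the three cross-validation protocols.

Protocols: stratified k-fold over segments, leave-one-trial-out, and
leave-one-subject-out.  Training uses Adam on the mean cross-entropy with
early stopping on a held-out slice of each training split (never the test
fold), restoring the best weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from damgcn.features import DEFeatureTensor
from damgcn.model import DAMGCNModel, ModelConfig, cross_entropy, predict
from damgcn.montage import ElectrodeGraph
from damgcn.nn import Adam

__all__ = [
    "TrainConfig",
    "EvalResult",
    "FoldRecord",
    "kfold_splits",
    "leave_one_trial_out",
    "leave_one_subject_out",
    "train",
    "train_single",
    "confusion",
    "accuracy_score",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (published defaults)."""

    max_epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 30          # early-stop patience on validation accuracy
    val_fraction: float = 0.1   # held-out-within-train slice for early stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size, self.patience) <= 0:
            raise ValueError("max_epochs, batch_size, patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class FoldRecord:
    accuracy: float
    confusion: np.ndarray
    epochs_run: int
    best_epoch: int
    gate_history: np.ndarray | None  # (epochs+1, F): epoch-0 row is pre-training
    model: DAMGCNModel | None = None


@dataclass
class EvalResult:
    protocol: str
    fold_accuracies: np.ndarray
    confusion_counts: np.ndarray  # summed over folds
    folds: list[FoldRecord] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    @property
    def confusion_percent(self) -> np.ndarray:
        return _row_percent(self.confusion_counts)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def _check_disjoint(splits):
    for tr, te in splits:
        if np.intersect1d(tr, te).size:
            raise AssertionError("train/test overlap detected")
    return splits


def kfold_splits(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold over samples; falls back to unstratified if a class
    has fewer than k members."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"{n} samples cannot form {k} folds")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() >= k:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = [(tr, te) for tr, te in skf.split(np.zeros(n), labels)]
    else:
        warnings.warn("a class has fewer samples than folds; unstratified split")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        splits = [
            (np.setdiff1d(perm, fold), np.sort(fold))
            for fold in np.array_split(perm, k)
        ]
    return _check_disjoint(splits)


def leave_one_trial_out(sample_index: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """One split per trial: all of that trial's segments form the test set."""
    trials = np.asarray(sample_index)[:, 0]
    unique = np.unique(trials)
    if len(unique) < 2:
        raise ValueError("leave-one-trial-out needs at least 2 trials")
    all_idx = np.arange(len(trials))
    splits = [(all_idx[trials != t], all_idx[trials == t]) for t in unique]
    return _check_disjoint(splits)


def leave_one_subject_out(subject_ids: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """One split per subject."""
    subjects = np.asarray(subject_ids)
    unique = np.unique(subjects)
    if len(unique) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    all_idx = np.arange(len(subjects))
    splits = [(all_idx[subjects != s], all_idx[subjects == s]) for s in unique]
    return _check_disjoint(splits)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def accuracy_score(preds: np.ndarray, labels: np.ndarray) -> float:
    """(TP + TN) / total — fraction of correct predictions."""
    preds, labels = np.asarray(preds), np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    return float(np.mean(preds == labels))


def confusion(
    preds: np.ndarray, labels: np.ndarray, num_classes: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Confusion counts (rows = true class) and row-normalized percentages."""
    preds, labels = np.asarray(preds), np.asarray(labels)
    if len(preds) == 0:
        raise ValueError("empty predictions")
    if num_classes is None:
        num_classes = int(max(preds.max(), labels.max())) + 1
    counts = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(counts, (labels, preds), 1)
    return counts, _row_percent(counts)


def _row_percent(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * counts / totals, 0.0)
    return pct


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _stratified_val_split(labels, frac, rng):
    idx = np.arange(len(labels))
    val = []
    for cls in np.unique(labels):
        cls_idx = rng.permutation(idx[labels == cls])
        n_val = max(1, int(round(frac * len(cls_idx))))
        if n_val >= len(cls_idx):
            n_val = len(cls_idx) - 1 if len(cls_idx) > 1 else 0
        val.extend(cls_idx[:n_val])
    val = np.sort(np.asarray(val, dtype=int))
    return np.setdiff1d(idx, val), val


def train_single(
    features: np.ndarray,
    labels: np.ndarray,
    graph: ElectrodeGraph | None,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int | None = None,
    record_gate: bool = True,
    early_stop: bool = True,
) -> tuple[DAMGCNModel, FoldRecord]:
    """Train one model on (features, labels) with internal early stopping.

    Returns the trained model (best weights restored) and a record of the
    run.  Fully deterministic for a given seed.  With ``early_stop=False``
    the model trains on all samples for the full epoch budget and the final
    weights are kept — the mode used for attention/gate interpretability,
    which needs the late-training state rather than the accuracy-optimal one.
    """
    seed = train_config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    features = np.asarray(features, dtype=float)

    if early_stop:
        tr_idx, val_idx = _stratified_val_split(labels, train_config.val_fraction, rng)
    else:
        tr_idx = np.arange(len(labels))
        val_idx = tr_idx
    x_tr, y_tr = features[tr_idx], labels[tr_idx]
    x_val, y_val = features[val_idx], labels[val_idx]

    model = DAMGCNModel(model_config, seed=seed)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)

    gate_hist = []
    if record_gate and model_config.use_dam:
        gate_hist.append(model.band_gate_proportions())

    best_val, best_state, best_epoch = -1.0, None, 0
    epochs_run = 0
    for epoch in range(1, train_config.max_epochs + 1):
        epochs_run = epoch
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            if len(batch) < 2 and model_config.use_gcn:
                continue  # batch-norm needs >= 2 samples
            logits, _ = model.forward(
                x_tr[batch], graph, training=True, rng=rng
            )
            loss = cross_entropy(logits, y_tr[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"loss diverged (non-finite) at epoch {epoch}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()

        if record_gate and model_config.use_dam:
            gate_hist.append(model.band_gate_proportions())

        if not early_stop:
            continue
        val_logits, _ = model.forward(x_val, graph, training=False)
        val_acc = accuracy_score(predict(val_logits), y_val)
        if val_acc > best_val + 1e-12:
            best_val, best_epoch = val_acc, epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        elif epoch - best_epoch >= train_config.patience:
            break

    if early_stop and best_state is not None:
        model.load_state_arrays(best_state)
    if not early_stop:
        final_logits, _ = model.forward(x_val, graph, training=False)
        best_val = accuracy_score(predict(final_logits), y_val)
        best_epoch = epochs_run

    record = FoldRecord(
        accuracy=best_val,
        confusion=np.zeros((model_config.num_classes,) * 2, dtype=int),
        epochs_run=epochs_run,
        best_epoch=best_epoch,
        gate_history=np.asarray(gate_hist) if gate_hist else None,
    )
    return model, record


def train(
    tensor: DEFeatureTensor,
    splits: list[tuple[np.ndarray, np.ndarray]],
    graph: ElectrodeGraph | None,
    model_config: ModelConfig,
    train_config: TrainConfig,
    protocol: str = "custom",
    keep_models: bool = False,
    early_stop: bool = True,
) -> EvalResult:
    """Cross-validated training: one freshly initialized model per split."""
    features = tensor.features
    labels = np.asarray(tensor.labels)
    n_classes = model_config.num_classes
    accs, folds = [], []
    total_confusion = np.zeros((n_classes, n_classes), dtype=int)

    for fold_id, (tr, te) in enumerate(splits):
        if np.intersect1d(tr, te).size:
            raise AssertionError(f"fold {fold_id}: train/test overlap")
        model, record = train_single(
            features[tr],
            labels[tr],
            graph,
            model_config,
            train_config,
            seed=train_config.seed + fold_id,
            early_stop=early_stop,
        )
        logits, _ = model.forward(features[te], graph, training=False)
        preds = predict(logits)
        record.accuracy = accuracy_score(preds, labels[te])
        counts, _ = confusion(preds, labels[te], num_classes=n_classes)
        record.confusion = counts
        if keep_models:
            record.model = model
        total_confusion += counts
        accs.append(record.accuracy)
        folds.append(record)

    return EvalResult(
        protocol=protocol,
        fold_accuracies=np.asarray(accs),
        confusion_counts=total_confusion,
        folds=folds,
    )
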