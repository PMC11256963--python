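"""Training loop, data splitting, cross-validation, and metrics.

Splits are stratified by label and fully seeded. The optimizer is Adam
with decoupled weight decay; early stopping monitors validation AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .bcm import fragment_drug
from .cfm import fragment_protein
from .errors import DivergenceError, InvalidInputError, InvalidParameterError
from .model import FMCAModel, ModelConfig, bce_loss
from .nn import Adam
from .vocab import Vocab, build_vocab, encode

__all__ = [
    "TrainConfig",
    "EvalMetrics",
    "compute_metrics",
    "split_dataset",
    "fold_indices",
    "cross_validate",
    "train",
    "prepare_encoded",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (published defaults: lr 1e-5,
    batch 64, weight decay 1e-4, dropout 0.1)."""

    lr: float = 1e-5
    batch_size: int = 64
    weight_decay: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    split_ratio: float = 0.8

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise InvalidParameterError(
                f"split_ratio must be in (0, 1), got {self.split_ratio}"
            )
        if self.patience > self.max_epochs:
            raise InvalidParameterError("patience must not exceed max_epochs")


@dataclass
class EvalMetrics:
    """AUC, AUPR, accuracy, precision, recall for one evaluation.

    Threshold-based metrics use 0.5 with scores at the threshold counted
    as positive predictions. AUC/AUPR are NaN when only one class is
    present.
    """

    auc: float
    aupr: float
    accuracy: float
    precision: float
    recall: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
        }


def compute_metrics(scores, labels) -> EvalMetrics:
    """Score a set of predicted probabilities against binary labels."""
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).reshape(-1).astype(int)
    if scores.shape != labels.shape:
        raise InvalidInputError(
            f"scores and labels differ in length: {scores.size} vs {labels.size}"
        )
    if scores.size == 0:
        raise InvalidInputError("cannot compute metrics on an empty set")
    both_classes = len(np.unique(labels)) == 2
    auc = float(roc_auc_score(labels, scores)) if both_classes else float("nan")
    aupr = (
        float(average_precision_score(labels, scores)) if both_classes else float("nan")
    )
    pred = (scores >= 0.5).astype(int)
    accuracy = float((pred == labels).mean())
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvalMetrics(auc, aupr, accuracy, float(precision), float(recall))


def _labels_of(pairs) -> np.ndarray:
    if isinstance(pairs, pd.DataFrame):
        return pairs["label"].to_numpy()
    return np.asarray([p[-1] for p in pairs])


def _take(pairs, idx):
    if isinstance(pairs, pd.DataFrame):
        return pairs.iloc[idx].reset_index(drop=True)
    return [pairs[i] for i in idx]


def split_dataset(pairs, ratio: float = 0.8, seed: int = 0):
    """Stratified, reproducible train/test split (default 8:2).

    ``pairs`` is a DataFrame with a ``label`` column or a sequence of
    tuples whose last element is the label. Returns (train, test) of the
    same type; disjoint and exhaustive.
    """
    labels = _labels_of(pairs)
    if len(labels) < 5:
        raise InvalidInputError(f"need at least 5 pairs to split, got {len(labels)}")
    if not 0.0 < ratio < 1.0:
        raise InvalidParameterError(f"ratio must be in (0, 1), got {ratio}")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, random_state=seed, stratify=labels, shuffle=True
    )
    return _take(pairs, np.sort(train_idx)), _take(pairs, np.sort(test_idx))


def fold_indices(labels, folds: int = 5, seed: int = 0):
    """Stratified fold assignment: list of (train_idx, val_idx) arrays."""
    if folds < 2:
        raise InvalidParameterError(f"need at least 2 folds, got {folds}")
    labels = np.asarray(labels)
    if len(labels) < folds:
        raise InvalidInputError(f"fewer pairs ({len(labels)}) than folds ({folds})")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# dataset preparation


def prepare_encoded(
    df: pd.DataFrame,
    config: ModelConfig,
    drug_vocab: Vocab | None = None,
    protein_vocab: Vocab | None = None,
    k: int = 3,
    patterns=None,
    category_table=None,
):
    """Fragment and encode an interaction table into id arrays.

    Vocabularies are built from this table when not supplied (pass the
    training-split vocabularies when encoding validation/test data so
    unseen fragments hit the unk id). Fragmentation is cached per unique
    string.
    """
    drug_cache: dict[str, object] = {}
    protein_cache: dict[str, object] = {}
    drug_seqs, protein_seqs = [], []
    for smiles, sequence in zip(df["smiles"], df["sequence"]):
        if smiles not in drug_cache:
            drug_cache[smiles] = fragment_drug(smiles, patterns=patterns)
        if sequence not in protein_cache:
            protein_cache[sequence] = fragment_protein(sequence, category_table, k=k)
        drug_seqs.append(drug_cache[smiles])
        protein_seqs.append(protein_cache[sequence])
    if drug_vocab is None:
        drug_vocab = build_vocab(drug_seqs)
    if protein_vocab is None:
        protein_vocab = build_vocab(protein_seqs)
    drug_ids = np.stack([encode(s, drug_vocab, config.drug_max_len) for s in drug_seqs])
    protein_ids = np.stack(
        [encode(s, protein_vocab, config.protein_max_len) for s in protein_seqs]
    )
    labels = df["label"].to_numpy().astype(int)
    return drug_ids, protein_ids, labels, drug_vocab, protein_vocab


# ---------------------------------------------------------------------------
# training


def train(
    model: FMCAModel,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    config: TrainConfig,
) -> list[dict]:
    """Mini-batch BCE optimization with early stopping on validation AUC.

    Returns the per-epoch history; the model is left holding the best
    validation-epoch parameters (or the final ones without validation).
    Raises :class:`DivergenceError` on a non-finite loss.
    """
    drug_ids, protein_ids, labels = train_data
    if len(labels) == 0 or (val_data is not None and len(val_data[2]) == 0):
        raise InvalidInputError("empty training or validation set")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(
        model.parameters(), lr=config.lr, weight_decay=config.weight_decay
    )
    history: list[dict] = []
    best_auc, best_state, since_best = -np.inf, None, 0
    n = len(labels)
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            probs = model.forward(drug_ids[batch], protein_ids[batch])
            loss = bce_loss(probs, labels[batch])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_data is not None:
            val_scores = model.predict_proba(val_data[0], val_data[1])
            val_metrics = compute_metrics(val_scores, val_data[2])
            record.update({f"val_{k}": v for k, v in val_metrics.as_dict().items()})
            auc = val_metrics.auc
            if np.isfinite(auc) and auc > best_auc:
                best_auc, best_state, since_best = auc, model.state_dict(), 0
            else:
                since_best += 1
        history.append(record)
        if val_data is not None and since_best >= config.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def cross_validate(
    train_set: pd.DataFrame,
    model_config: ModelConfig,
    train_config: TrainConfig,
    folds: int = 5,
    k: int = 3,
    patterns=None,
) -> tuple[list[EvalMetrics], EvalMetrics]:
    """Stratified k-fold cross-validation over an interaction table.

    Each fold serves as the validation set exactly once; fold-train
    vocabularies are rebuilt per fold so validation fragments unseen in
    training hit the unk id. Returns (per-fold metrics, mean metrics);
    NaN metrics are skipped in the mean with a warning.
    """
    labels = _labels_of(train_set)
    per_fold: list[EvalMetrics] = []
    for fold, (tr_idx, va_idx) in enumerate(
        fold_indices(labels, folds=folds, seed=train_config.seed)
    ):
        tr_df, va_df = _take(train_set, tr_idx), _take(train_set, va_idx)
        if len(np.unique(_labels_of(va_df))) < 2:
            warnings.warn(f"fold {fold} has a single class; AUC/AUPR undefined")
        d_tr, p_tr, y_tr, dvocab, pvocab = prepare_encoded(
            tr_df, model_config, k=k, patterns=patterns
        )
        d_va, p_va, y_va, _, _ = prepare_encoded(
            va_df, model_config, drug_vocab=dvocab, protein_vocab=pvocab,
            k=k, patterns=patterns,
        )
        model = FMCAModel(
            model_config, dvocab.size, pvocab.size, seed=train_config.seed + fold
        )
        train(model, (d_tr, p_tr, y_tr), (d_va, p_va, y_va), train_config)
        scores = model.predict_proba(d_va, p_va)
        per_fold.append(compute_metrics(scores, y_va))
    fields = ["auc", "aupr", "accuracy", "precision", "recall"]
    means = {}
    for f in fields:
        vals = [getattr(m, f) for m in per_fold if np.isfinite(getattr(m, f))]
        means[f] = float(np.mean(vals)) if vals else float("nan")
    return per_fold, EvalMetrics(**means)
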