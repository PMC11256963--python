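"""The canonical desk-scale synthetic benchmark experiment.

Generates a planted-rule dataset, trains the small configuration, and
reports held-out metrics. Shared by the acceptance tests and the
reporting script so both exercise exactly the same code path.

Training runs in float32 (about half the single-CPU wall time of
float64 with no measurable effect on the learned AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .autograd import default_dtype
from .model import FMCAModel, ModelConfig
from .synth import PlantedRule, generate_dataset
from .train import (
    EvalMetrics,
    TrainConfig,
    compute_metrics,
    prepare_encoded,
    split_dataset,
    train,
)

__all__ = ["SyntheticRunResult", "run_synthetic_experiment"]

#: protein k-gram size for the experiment. k=1 (per-residue categories)
#: is used instead of the k=3 default: with only a few hundred training
#: pairs the ~500-type trigram vocabulary lets the model memorize
#: individual proteins instead of learning the planted motif, while the
#: 8-letter category alphabet forces generalization.
EXPERIMENT_K = 1


@dataclass
class SyntheticRunResult:
    metrics: EvalMetrics
    epochs: int
    n_train: int
    n_test: int
    ablation: str


def run_synthetic_experiment(
    seed: int,
    n: int = 400,
    ablation: str = "full",
    max_epochs: int = 50,
    rule: PlantedRule | None = None,
) -> SyntheticRunResult:
    """Train the small model on an n-pair planted-rule dataset.

    The dataset is split 8:2 into train/test; a quarter of the training
    split is held out for early stopping on validation AUC. Fully
    deterministic for a fixed seed.
    """
    if rule is None:
        rule = PlantedRule()
    rows = generate_dataset(n, rule=rule, rng=seed)
    df = pd.DataFrame(rows, columns=["smiles", "sequence", "label"])
    with default_dtype("float32"):
        model_cfg = ModelConfig.small(
            drug_max_len=32, protein_max_len=403, dropout=0.2, ablation=ablation
        )
        train_cfg = TrainConfig(
            lr=2e-3,
            batch_size=64,
            weight_decay=1e-3,
            max_epochs=max_epochs,
            patience=15,
            seed=seed,
        )
        train_df, test_df = split_dataset(df, ratio=train_cfg.split_ratio, seed=seed)
        fit_df, val_df = split_dataset(train_df, ratio=0.75, seed=seed)
        d_tr, p_tr, y_tr, dvocab, pvocab = prepare_encoded(
            fit_df, model_cfg, k=EXPERIMENT_K
        )
        d_va, p_va, y_va, _, _ = prepare_encoded(
            val_df, model_cfg, drug_vocab=dvocab, protein_vocab=pvocab, k=EXPERIMENT_K
        )
        d_te, p_te, y_te, _, _ = prepare_encoded(
            test_df, model_cfg, drug_vocab=dvocab, protein_vocab=pvocab, k=EXPERIMENT_K
        )
        model = FMCAModel(model_cfg, dvocab.size, pvocab.size, seed=seed)
        history = train(model, (d_tr, p_tr, y_tr), (d_va, p_va, y_va), train_cfg)
        metrics = compute_metrics(model.predict_proba(d_te, p_te), y_te)
    return SyntheticRunResult(
        metrics=metrics,
        epochs=len(history),
        n_train=len(y_tr),
        n_test=len(y_te),
        ablation=ablation,
    )
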