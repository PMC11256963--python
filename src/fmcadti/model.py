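"""The FMCA architecture: embedding, CNN blocks, shared-weight multihead
cross attention with residual mixing, and the pooled FCN classifier head.

Two ablation variants are configuration switches, not separate classes:
``no_cross_attention`` removes the attention module entirely (CNN
features pass straight through), ``no_original_feature`` drops the
residual mix and keeps only the attention output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import InvalidInputError, InvalidParameterError, ShapeError
from .nn import (
    CNNBlock,
    Dropout,
    Embedding,
    Linear,
    Module,
    MultiheadCrossAttention,
)
from .vocab import Vocab

__all__ = [
    "ModelConfig",
    "FMCAModel",
    "residual_mix",
    "bce_loss",
    "save_checkpoint",
    "load_checkpoint",
]

ABLATIONS = ("full", "no_cross_attention", "no_original_feature")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the published full-scale settings (embedding 512,
    4 heads, drug kernels 3/3/3, protein kernels 4/6/8, dropout 0.1);
    ``small()`` gives a desk-scale variant used throughout the tests.
    """

    emb_dim: int = 512
    conv_channels: int = 128
    drug_kernels: tuple[int, int, int] = (3, 3, 3)
    protein_kernels: tuple[int, int, int] = (4, 6, 8)
    heads: int = 4
    dropout: float = 0.1
    fcn_hidden: tuple[int, int] = (512, 128)
    alpha_elu: float = 1.0
    mix_weight: float = 0.5
    ablation: str = "full"
    drug_max_len: int = 100
    protein_max_len: int = 545

    def __post_init__(self):
        if self.conv_channels % self.heads != 0:
            raise InvalidParameterError(
                f"conv_channels {self.conv_channels} must be divisible by "
                f"heads {self.heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidParameterError(f"dropout must be in [0, 1), got {self.dropout}")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise InvalidParameterError(
                f"mix_weight must be in [0, 1], got {self.mix_weight}"
            )
        if self.ablation not in ABLATIONS:
            raise InvalidParameterError(
                f"ablation must be one of {ABLATIONS}, got {self.ablation!r}"
            )

    @property
    def d_head(self) -> int:
        return self.conv_channels // self.heads

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """A small configuration for CPU-scale experiments and tests."""
        base = dict(
            emb_dim=32,
            conv_channels=32,
            heads=4,
            fcn_hidden=(64, 32),
            drug_max_len=32,
            protein_max_len=134,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_kernels"] = list(d["drug_kernels"])
        d["protein_kernels"] = list(d["protein_kernels"])
        d["fcn_hidden"] = list(d["fcn_hidden"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("drug_kernels", "protein_kernels", "fcn_hidden"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_ablation(self, ablation: str) -> "ModelConfig":
        return replace(self, ablation=ablation)


def residual_mix(m: Tensor, original: Tensor, w: float = 0.5, ablation: str = "full"):
    """Convex mix of the attention feature with the original CNN feature.

    Returns ``w*m + (1-w)*original``; under the no-original-feature
    ablation the attention output passes through unchanged.
    """
    if m.shape != original.shape:
        raise ShapeError(f"shape mismatch {m.shape} vs {original.shape}")
    if ablation == "no_original_feature":
        return m
    return m * w + original * (1.0 - w)


def bce_loss(p: Tensor, y, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with probability clamping at ``eps``."""
    y = np.asarray(getattr(y, "data", y), dtype=np.float64).reshape(-1)
    pd = p.data.reshape(-1)
    if pd.shape != y.shape:
        raise InvalidInputError(
            f"predictions and labels differ in length: {pd.shape} vs {y.shape}"
        )
    pc = np.clip(pd, eps, 1.0 - eps)
    losses = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    out_data = losses.mean()
    if not p.requires_grad:
        return Tensor(out_data)
    inside = (pd > eps) & (pd < 1.0 - eps)

    def backward(g):
        dp = np.where(inside, (pc - y) / (pc * (1.0 - pc)), 0.0) / y.size
        p.accumulate((g * dp).reshape(p.data.shape))

    return Tensor(out_data, True, (p,), backward)


class FMCAModel(Module):
    """End-to-end fragment-level interaction classifier."""

    def __init__(
        self,
        config: ModelConfig,
        drug_vocab_size: int,
        protein_vocab_size: int,
        seed: int = 0,
    ):
        super().__init__()
        self.config = config
        self.drug_vocab_size = drug_vocab_size
        self.protein_vocab_size = protein_vocab_size
        self.init_seed = seed
        rng = np.random.default_rng(seed)
        self.rng = rng  # dropout noise source

        d = config.conv_channels
        self.drug_embedding = Embedding(rng, drug_vocab_size, config.emb_dim)
        self.protein_embedding = Embedding(rng, protein_vocab_size, config.emb_dim)
        self.drug_cnn = CNNBlock(
            rng, config.emb_dim, d, config.drug_kernels, config.alpha_elu
        )
        self.protein_cnn = CNNBlock(
            rng, config.emb_dim, d, config.protein_kernels, config.alpha_elu
        )
        if config.ablation != "no_cross_attention":
            self.cross_attention = MultiheadCrossAttention(rng, d, config.heads)
        h1, h2 = config.fcn_hidden
        self.drop1 = Dropout(config.dropout, rng)
        self.fc1 = Linear(rng, 2 * d, h1)
        self.drop2 = Dropout(config.dropout, rng)
        self.fc2 = Linear(rng, h1, h2)
        self.fc3 = Linear(rng, h2, 1)

    # ---- forward pieces --------------------------------------------------

    def encode_features(self, drug_ids, protein_ids):
        """Embedding + CNN blocks; returns (D_CNN, P_CNN)."""
        drug_ids = np.atleast_2d(np.asarray(drug_ids, dtype=np.int64))
        protein_ids = np.atleast_2d(np.asarray(protein_ids, dtype=np.int64))
        d_cnn = self.drug_cnn(self.drug_embedding(drug_ids))
        p_cnn = self.protein_cnn(self.protein_embedding(protein_ids))
        return d_cnn, p_cnn

    def interaction_features(self, d_cnn: Tensor, p_cnn: Tensor):
        """Cross attention + residual mix; returns (D_f, P_f)."""
        cfg = self.config
        if cfg.ablation == "no_cross_attention":
            return d_cnn, p_cnn
        m_d, m_p = self.cross_attention(d_cnn, p_cnn)
        d_f = residual_mix(m_d, d_cnn, cfg.mix_weight, cfg.ablation)
        p_f = residual_mix(m_p, p_cnn, cfg.mix_weight, cfg.ablation)
        return d_f, p_f

    def predict_head(self, d_f: Tensor, p_f: Tensor) -> Tensor:
        """Adaptive max pooling, concatenation, and the 3-layer FCN.

        Returns a probability per sample, strictly inside (0, 1).
        """
        d_pool = ag.max_along(d_f, axis=1)
        p_pool = ag.max_along(p_f, axis=1)
        x = ag.concat([d_pool, p_pool], axis=-1)
        x = ag.leaky_relu(self.fc1(self.drop1(x)))
        x = ag.leaky_relu(self.fc2(self.drop2(x)))
        logit = self.fc3(x)
        return ag.reshape(ag.sigmoid(logit), (logit.shape[0],))

    def forward(self, drug_ids, protein_ids) -> Tensor:
        d_cnn, p_cnn = self.encode_features(drug_ids, protein_ids)
        d_f, p_f = self.interaction_features(d_cnn, p_cnn)
        return self.predict_head(d_f, p_f)

    # ---- inference helper ------------------------------------------------

    def predict_proba(self, drug_ids, protein_ids, batch_size: int = 64) -> np.ndarray:
        """Eval-mode probabilities as a plain array, in minibatches."""
        was_training = self.training
        self.eval()
        drug_ids = np.atleast_2d(np.asarray(drug_ids, dtype=np.int64))
        protein_ids = np.atleast_2d(np.asarray(protein_ids, dtype=np.int64))
        out = []
        for start in range(0, drug_ids.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            out.append(self.forward(drug_ids[sl], protein_ids[sl]).data)
        if was_training:
            self.train()
        return np.concatenate(out)


def save_checkpoint(path, model: FMCAModel, drug_vocab: Vocab, protein_vocab: Vocab):
    """Serialize parameters, config, and both vocabularies to one .npz."""
    meta = {
        "config": model.config.to_dict(),
        "drug_vocab": drug_vocab.token_to_id,
        "protein_vocab": protein_vocab.token_to_id,
        "init_seed": model.init_seed,
    }
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[FMCAModel, Vocab, Vocab]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {
            k[len("state/") :]: data[k] for k in data.files if k.startswith("state/")
        }
    config = ModelConfig.from_dict(meta["config"])
    drug_vocab = Vocab(token_to_id=meta["drug_vocab"])
    protein_vocab = Vocab(token_to_id=meta["protein_vocab"])
    model = FMCAModel(
        config, drug_vocab.size, protein_vocab.size, seed=meta.get("init_seed", 0)
    )
    model.load_state_dict(state)
    model.eval()
    return model, drug_vocab, protein_vocab
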