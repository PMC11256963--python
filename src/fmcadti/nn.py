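"""Neural-network layers on top of the autograd engine.

Layout convention: sequence tensors are (batch, length, channels).
Every layer takes an explicit ``numpy.random.Generator`` for parameter
initialization so that model construction is fully seeded.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor
from .errors import ShapeError

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "Conv1d",
    "BatchNorm1d",
    "Dropout",
    "CNNBlock",
    "MultiheadCrossAttention",
    "Adam",
]


class Module:
    """Tiny module base: parameter/buffer discovery, train/eval mode."""

    def __init__(self):
        self.training = True
        self._buffers: list[str] = []

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        dtype = ag.get_default_dtype()
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=dtype).reshape(p.data.shape)
        modules = {"": self}
        for name, child in self._walk_modules():
            modules[name] = child
        for name, _ in list(self.named_buffers()):
            prefix, _, attr = name.rpartition(".")
            setattr(modules[prefix], attr, np.asarray(state[name], dtype=dtype))

    def _walk_modules(self, prefix: str = ""):
        for name, child in self._children():
            full = prefix + name
            yield full, child
            yield from child._walk_modules(full + ".")


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_features: int, out_features: int):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class Embedding(Module):
    """Integer-id lookup table with gradient scatter-add."""

    def __init__(self, rng: np.random.Generator, num_embeddings: int, dim: int):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0, (num_embeddings, dim)))

    def forward(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.min(initial=0) < 0 or ids.max(initial=0) >= self.weight.data.shape[0]:
            raise ShapeError("embedding id out of range")
        weight = self.weight
        out_data = weight.data[ids]

        def backward(g):
            gw = np.zeros_like(weight.data)
            np.add.at(gw, ids, g)
            weight.accumulate(gw)

        return Tensor(out_data, True, (weight,), backward)


class Conv1d(Module):
    """1D convolution over the length axis with same-length zero padding.

    Implemented as im2col + matmul; the weight is stored flattened as
    (kernel * in_channels, out_channels).
    """

    def __init__(
        self,
        rng: np.random.Generator,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        pad: bool = True,
    ):
        super().__init__()
        self.kernel_size = int(kernel_size)
        self.in_channels = in_channels
        self.pad = pad
        fan_in = self.kernel_size * in_channels
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (fan_in, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.data.shape
        if C != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} channels, got {C}")
        K = self.kernel_size
        if self.pad:
            pl, pr = (K - 1) // 2, K // 2
        else:
            pl = pr = 0
            if L < K:
                raise ShapeError(f"length {L} shorter than kernel {K} without padding")
        L_out = L + pl + pr - K + 1
        xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
        cols = np.stack([xp[:, i : i + L_out, :] for i in range(K)], axis=2)
        cols = cols.reshape(B, L_out, K * C)
        weight, bias = self.weight, self.bias
        out_data = cols @ weight.data + bias.data

        def backward(g):
            if bias.requires_grad:
                bias.accumulate(g.sum(axis=(0, 1)))
            if weight.requires_grad:
                weight.accumulate(
                    cols.reshape(-1, K * C).T @ g.reshape(-1, g.shape[-1])
                )
            if x.requires_grad:
                gcols = (g @ weight.data.T).reshape(B, L_out, K, C)
                gxp = np.zeros_like(xp)
                for i in range(K):
                    gxp[:, i : i + L_out, :] += gcols[:, :, i, :]
                x.accumulate(gxp[:, pl : pl + L, :])

        parents = (x, weight, bias) if x.requires_grad else (weight, bias)
        return Tensor(out_data, True, parents, backward)


class BatchNorm1d(Module):
    """Per-channel batch normalization over the batch and length axes."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        dtype = ag.get_default_dtype()
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels, dtype=dtype)
        self.running_var = np.ones(num_channels, dtype=dtype)
        self._buffers = ["running_mean", "running_var"]

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            axes = tuple(range(x.data.ndim - 1))
            n = int(np.prod([x.data.shape[a] for a in axes]))
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
        else:
            mean, var = self.running_mean, self.running_var
            n = None
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * ivstd
        out_data = gamma.data * xhat + beta.data

        training = self.training

        def backward(g):
            if beta.requires_grad:
                beta.accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
            if gamma.requires_grad:
                gamma.accumulate((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0))
            if x.requires_grad:
                dxhat = g * gamma.data
                if training:
                    axes = tuple(range(x.data.ndim - 1))
                    m1 = dxhat.mean(axis=axes)
                    m2 = (dxhat * xhat).mean(axis=axes)
                    x.accumulate(ivstd * (dxhat - m1 - xhat * m2))
                else:
                    x.accumulate(dxhat * ivstd)

        parents = (x, gamma, beta) if x.requires_grad else (gamma, beta)
        return Tensor(out_data, True, parents, backward)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Needs the model rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ShapeError(f"dropout must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class CNNBlock(Module):
    """Three stacked (1D conv -> batch norm -> ELU) layers.

    Same-length padding keeps the sequence axis fixed so the attention
    shapes downstream are static.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        in_dim: int,
        out_channels: int,
        kernels: tuple[int, int, int],
        alpha_elu: float = 1.0,
    ):
        super().__init__()
        self.alpha_elu = alpha_elu
        dims = [in_dim, out_channels, out_channels]
        self.convs = [
            Conv1d(rng, d, out_channels, k) for d, k in zip(dims, kernels)
        ]
        self.norms = [BatchNorm1d(out_channels) for _ in kernels]

    def forward(self, x: Tensor) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = ag.elu(norm(conv(x)), alpha=self.alpha_elu)
        return x


class MultiheadCrossAttention(Module):
    """Shared-weight multihead cross attention.

    One set of Q/K/V projections serves both directions: the drug pass
    uses drug features as queries against protein keys/values, the
    protein pass swaps the roles — with the *same parameter objects*,
    not copies. Heads are concatenated and projected by a shared output
    matrix.
    """

    def __init__(self, rng: np.random.Generator, d_model: int, heads: int):
        super().__init__()
        if d_model % heads != 0:
            raise ShapeError(f"channel dim {d_model} not divisible by {heads} heads")
        self.d_model = d_model
        self.heads = heads
        self.d_head = d_model // heads
        bound = 1.0 / math.sqrt(d_model)

        def mat():
            return Parameter(rng.uniform(-bound, bound, (d_model, d_model)))

        self.w_q, self.w_k, self.w_v, self.w_o = mat(), mat(), mat(), mat()

    def _split_heads(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        return ag.swapaxes(ag.reshape(x, (B, L, self.heads, self.d_head)), 1, 2)

    def _merge_heads(self, x: Tensor) -> Tensor:
        B, _, L, _ = x.shape
        return ag.reshape(ag.swapaxes(x, 1, 2), (B, L, self.d_model))

    def _attend(self, query: Tensor, context: Tensor):
        q = self._split_heads(ag.matmul(query, self.w_q))
        k = self._split_heads(ag.matmul(context, self.w_k))
        v = self._split_heads(ag.matmul(context, self.w_v))
        scores = ag.matmul(q, ag.swapaxes(k, -1, -2)) * (1.0 / math.sqrt(self.d_head))
        attn = ag.softmax(scores, axis=-1)
        z = ag.matmul(attn, v)
        return ag.matmul(self._merge_heads(z), self.w_o), attn

    def forward(self, drug: Tensor, protein: Tensor, return_attention: bool = False):
        if drug.shape[-1] != self.d_model or protein.shape[-1] != self.d_model:
            raise ShapeError(
                f"expected channel dim {self.d_model}, got "
                f"{drug.shape[-1]} / {protein.shape[-1]}"
            )
        m_drug, a_drug = self._attend(drug, protein)
        m_protein, a_protein = self._attend(protein, drug)
        if return_attention:
            return m_drug, m_protein, a_drug, a_protein
        return m_drug, m_protein


class Adam:
    """Adam with decoupled weight decay (AdamW-style)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
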