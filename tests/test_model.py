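"""Model-level behavior: cross attention vs a naive oracle, weight
sharing, residual mixing, the prediction head, the loss, and end-to-end
forward contracts."""

import math

import numpy as np
import pytest

from fmcadti.autograd import Tensor
from fmcadti.errors import InvalidInputError, InvalidParameterError, ShapeError
from fmcadti.model import (
    FMCAModel,
    ModelConfig,
    bce_loss,
    load_checkpoint,
    residual_mix,
    save_checkpoint,
)
from fmcadti.nn import MultiheadCrossAttention
from fmcadti.vocab import Vocab


def naive_cross_attention(D, P, wq, wk, wv, wo, heads):
    """Loop-over-everything reference for one (drug, protein) sample."""

    def one_direction(Q_in, KV_in):
        d = Q_in.shape[1]
        dh = d // heads
        z_heads = []
        for i in range(heads):
            wqi = wq[:, i * dh : (i + 1) * dh]
            wki = wk[:, i * dh : (i + 1) * dh]
            wvi = wv[:, i * dh : (i + 1) * dh]
            Q = Q_in @ wqi
            K = KV_in @ wki
            V = KV_in @ wvi
            scores = np.zeros((Q.shape[0], K.shape[0]))
            for a in range(Q.shape[0]):
                for b in range(K.shape[0]):
                    scores[a, b] = float(Q[a] @ K[b]) / math.sqrt(dh)
            attn = np.zeros_like(scores)
            for a in range(scores.shape[0]):
                e = np.exp(scores[a] - scores[a].max())
                attn[a] = e / e.sum()
            z_heads.append(attn @ V)
        return np.concatenate(z_heads, axis=1) @ wo

    return one_direction(D, P), one_direction(P, D)


class TestCrossAttention:
    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        attn = MultiheadCrossAttention(rng, d_model=8, heads=2)
        D = rng.normal(size=(1, 7, 8))
        P = rng.normal(size=(1, 11, 8))
        m_d, m_p = attn(Tensor(D), Tensor(P))
        exp_d, exp_p = naive_cross_attention(
            D[0], P[0], attn.w_q.data, attn.w_k.data, attn.w_v.data,
            attn.w_o.data, heads=2,
        )
        assert np.abs(m_d.data[0] - exp_d).max() <= 1e-5
        assert np.abs(m_p.data[0] - exp_p).max() <= 1e-5

    def test_attention_rows_normalized(self, rng):
        attn = MultiheadCrossAttention(rng, 16, 4)
        _, _, a_d, a_p = attn(
            Tensor(rng.normal(size=(3, 5, 16))),
            Tensor(rng.normal(size=(3, 9, 16))),
            return_attention=True,
        )
        assert np.allclose(a_d.data.sum(axis=-1), 1.0, atol=1e-6)
        assert np.allclose(a_p.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_key_degenerates_to_value(self, rng):
        attn = MultiheadCrossAttention(rng, 8, 2)
        D = rng.normal(size=(1, 4, 8))
        P = rng.normal(size=(1, 1, 8))
        m_d, _ = attn(Tensor(D), Tensor(P))
        # softmax over one key is 1, so Z = V = P @ Wv per head
        v = P[0] @ attn.w_v.data
        expected = np.repeat(v, 4, axis=0) @ attn.w_o.data
        assert np.allclose(m_d.data[0], expected, atol=1e-10)

    def test_weight_sharing_parameter_identity(self, rng):
        attn = MultiheadCrossAttention(rng, 8, 2)
        D = Tensor(rng.normal(size=(1, 3, 8)))
        P = Tensor(rng.normal(size=(1, 5, 8)))
        d0, p0 = attn(D, P)
        attn.w_q.data[0, 0] += 1.0  # single in-place perturbation
        d1, p1 = attn(D, P)
        assert not np.allclose(d0.data, d1.data)
        assert not np.allclose(p0.data, p1.data)

    def test_channel_mismatch(self, rng):
        attn = MultiheadCrossAttention(rng, 8, 2)
        with pytest.raises(ShapeError):
            attn(Tensor(np.zeros((1, 3, 8))), Tensor(np.zeros((1, 3, 6))))

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ShapeError):
            MultiheadCrossAttention(rng, 10, 4)


class TestResidualMix:
    def test_fixed_point(self, rng):
        m = Tensor(rng.normal(size=(3, 4)))
        out = residual_mix(m, m, 0.5)
        assert np.allclose(out.data, m.data, atol=1e-12)

    def test_zero_attention_halves(self, rng):
        orig = Tensor(rng.normal(size=(3, 4)))
        out = residual_mix(Tensor(np.zeros((3, 4))), orig, 0.5)
        assert np.allclose(out.data, 0.5 * orig.data, atol=1e-12)

    def test_arithmetic(self):
        out = residual_mix(Tensor([[2.0]]), Tensor([[4.0]]), 0.5)
        assert out.data.tolist() == [[3.0]]

    def test_no_original_feature_passthrough(self):
        m = Tensor([[2.0]])
        out = residual_mix(m, Tensor([[4.0]]), 0.5, ablation="no_original_feature")
        assert out is m

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            residual_mix(Tensor(np.zeros((2, 2))), Tensor(np.zeros((3, 2))))


class TestBceLoss:
    def test_half_probability_is_ln2(self):
        assert bce_loss(Tensor([0.5]), [1]).item() == pytest.approx(
            math.log(2), abs=1e-9
        )
        assert bce_loss(Tensor([0.5]), [0]).item() == pytest.approx(
            math.log(2), abs=1e-9
        )

    def test_perfect_prediction_near_zero(self):
        assert bce_loss(Tensor([1.0 - 1e-7]), [1]).item() == pytest.approx(0, abs=1e-6)

    def test_symmetry(self):
        assert bce_loss(Tensor([0.3]), [0]).item() == pytest.approx(
            bce_loss(Tensor([0.7]), [1]).item(), abs=1e-12
        )

    def test_clamping_keeps_loss_finite(self):
        assert np.isfinite(bce_loss(Tensor([0.0, 1.0]), [1, 0]).item())

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            bce_loss(Tensor([0.5, 0.5]), [1])

    def test_nonnegative(self, rng):
        p = Tensor(rng.uniform(0.01, 0.99, 20))
        y = rng.integers(0, 2, 20)
        assert bce_loss(p, y).item() >= 0


class TestModelConfig:
    def test_head_divisibility(self):
        with pytest.raises(InvalidParameterError):
            ModelConfig(conv_channels=30, heads=4)

    def test_ablation_validated(self):
        with pytest.raises(InvalidParameterError):
            ModelConfig(ablation="bogus")

    def test_published_defaults(self):
        cfg = ModelConfig()
        assert cfg.emb_dim == 512
        assert cfg.heads == 4
        assert cfg.drug_kernels == (3, 3, 3)
        assert cfg.protein_kernels == (4, 6, 8)
        assert cfg.dropout == 0.1

    def test_dict_roundtrip(self):
        cfg = ModelConfig.small(mix_weight=0.3)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


def tiny_model(ablation="full", seed=0):
    cfg = ModelConfig(
        emb_dim=12, conv_channels=8, heads=2, fcn_hidden=(8, 4),
        drug_max_len=6, protein_max_len=9, dropout=0.2, ablation=ablation,
    )
    return FMCAModel(cfg, drug_vocab_size=15, protein_vocab_size=20, seed=seed), cfg


def tiny_batch(rng, n=4):
    return (
        rng.integers(0, 15, (n, 6)),
        rng.integers(0, 20, (n, 9)),
        rng.integers(0, 2, n),
    )


class TestForward:
    def test_probabilities_in_open_interval(self, rng):
        model, _ = tiny_model()
        d, p, _ = tiny_batch(rng)
        out = model.predict_proba(d, p)
        assert np.all(out > 0) and np.all(out < 1)

    def test_eval_mode_deterministic(self, rng):
        model, _ = tiny_model()
        model.eval()
        d, p, _ = tiny_batch(rng)
        a = model.forward(d, p).data
        b = model.forward(d, p).data
        assert np.array_equal(a, b)

    def test_batched_equals_per_sample(self, rng):
        model, _ = tiny_model()
        model.eval()
        d, p, _ = tiny_batch(rng, n=5)
        batched = model.forward(d, p).data
        singles = np.array([model.forward(d[i : i + 1], p[i : i + 1]).data[0]
                            for i in range(5)])
        assert np.abs(batched - singles).max() <= 1e-6

    def test_ablation_changes_output(self, rng):
        full, _ = tiny_model("full")
        nocross, _ = tiny_model("no_cross_attention")
        full.eval(), nocross.eval()
        d, p, _ = tiny_batch(rng)
        assert not np.allclose(full.forward(d, p).data, nocross.forward(d, p).data)

    def test_no_cross_attention_has_no_attention_params(self):
        model, _ = tiny_model("no_cross_attention")
        names = [n for n, _ in model.named_parameters()]
        assert not any("cross_attention" in n for n in names)

    def test_pooling_row_permutation_invariant(self, rng):
        model, _ = tiny_model()
        model.eval()
        d_f = Tensor(rng.normal(size=(1, 6, 8)))
        p_f = Tensor(rng.normal(size=(1, 9, 8)))
        base = model.predict_head(d_f, p_f).data
        perm = Tensor(d_f.data[:, rng.permutation(6), :])
        assert np.allclose(model.predict_head(perm, p_f).data, base, atol=1e-12)

    def test_constant_rows_pool_to_constant(self, rng):
        model, _ = tiny_model()
        from fmcadti import autograd as ag

        const = Tensor(np.full((1, 6, 8), 3.14))
        pooled = ag.max_along(const, axis=1)
        assert np.allclose(pooled.data, 3.14)


class TestGradientSanity:
    def test_finite_difference_full_model(self, rng):
        model, _ = tiny_model()
        model.eval()  # freeze dropout/batch-norm noise for a pure function
        d, p, y = tiny_batch(rng, n=2)

        def value():
            return bce_loss(model.forward(d, p), y).item()

        loss = bce_loss(model.forward(d, p), y)
        model.zero_grad()
        loss.backward()
        eps = 1e-5
        checked = 0
        for name, param in model.named_parameters():
            flat = param.data.reshape(-1)
            gflat = param.grad.reshape(-1) if param.grad is not None else None
            for idx in [0, flat.size // 2]:
                orig = flat[idx]
                flat[idx] = orig + eps
                fp = value()
                flat[idx] = orig - eps
                fm = value()
                flat[idx] = orig
                num = (fp - fm) / (2 * eps)
                got = 0.0 if gflat is None else gflat[idx]
                assert got == pytest.approx(num, rel=1e-3, abs=1e-7), name
                checked += 1
        assert checked > 20


class TestCheckpoint:
    def test_roundtrip_predictions(self, tmp_path, rng):
        dvocab = Vocab(token_to_id={"CCO": 2, "=O": 3})
        pvocab = Vocab(token_to_id={"AAA": 2})
        cfg = ModelConfig(
            emb_dim=12, conv_channels=8, heads=2, fcn_hidden=(8, 4),
            drug_max_len=6, protein_max_len=9,
        )
        model = FMCAModel(cfg, dvocab.size, pvocab.size, seed=3)
        model.eval()
        d = rng.integers(0, dvocab.size, (4, 6))
        p = rng.integers(0, pvocab.size, (4, 9))
        before = model.predict_proba(d, p)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, dvocab, pvocab)
        loaded, dv2, pv2 = load_checkpoint(path)
        assert dv2.token_to_id == dvocab.token_to_id
        assert pv2.token_to_id == pvocab.token_to_id
        assert loaded.config == cfg
        after = loaded.predict_proba(d, p)
        assert np.allclose(before, after, atol=1e-12)
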