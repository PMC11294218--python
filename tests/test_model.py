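import math

import numpy as np
import pytest

from damgcn.model import (
    DAMGCNModel,
    ModelConfig,
    cross_entropy,
    gelu,
    load_model,
    predict,
    save_model,
)
from damgcn.montage import ElectrodeGraph, Montage, build_graph
from damgcn.nn import Parameter, Tensor


def tiny_config(**kw):
    base = dict(
        num_channels=5, num_bands=3, embedding_size=8, num_heads=2,
        num_encoders=1, num_classes=2, dropout=0.0, gcn_layers=2,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture()
def tiny_graph(rng):
    return build_graph(Montage(tuple("abcde"), rng.normal(size=(5, 3))))


class TestConfig:
    def test_head_dim_floors(self):
        cfg = ModelConfig(num_channels=4, num_bands=2, embedding_size=64,
                          num_heads=6, num_classes=2)
        assert cfg.head_dim == 10

    def test_defaults_match_published_table(self):
        cfg = ModelConfig(num_channels=62, num_bands=5, num_classes=3)
        assert cfg.embedding_size == 64
        assert cfg.num_encoders == 2
        assert cfg.num_heads == 6
        assert cfg.dropout == 0.5

    def test_invalid_dropout(self):
        with pytest.raises(ValueError):
            ModelConfig(num_channels=4, num_bands=2, num_classes=2, dropout=1.0)

    def test_too_many_heads(self):
        with pytest.raises(ValueError, match="heads"):
            ModelConfig(num_channels=4, num_bands=2, embedding_size=4,
                        num_heads=8, num_classes=2)


class TestGelu:
    def test_zero(self):
        assert gelu(Tensor(np.array([0.0]))).data[0] == 0.0

    def test_saturates(self):
        assert gelu(Tensor(np.array([10.0]))).data[0] == pytest.approx(10.0, abs=1e-6)

    def test_scalar_value(self):
        expected = 1.0 / (1.0 + math.exp(-1.702))
        assert gelu(Tensor(np.array([1.0]))).data[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.8458, abs=1e-4)


class TestBatchNorm:
    def test_standardized_input_passthrough(self, rng):
        model = DAMGCNModel(tiny_config(), seed=0)
        x = rng.normal(size=(64, 5, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        out = model.input_norm(Tensor(x), training=True)
        np.testing.assert_allclose(out.data, x, atol=1e-4)

    def test_constant_input_gives_beta(self):
        model = DAMGCNModel(tiny_config(), seed=0)
        model.input_norm.beta.data[:] = 1.5
        out = model.input_norm(Tensor(np.full((8, 5, 3), 7.0)), training=True)
        np.testing.assert_allclose(out.data, 1.5, atol=1e-2)

    def test_matches_dense_oracle(self, rng):
        model = DAMGCNModel(tiny_config(), seed=0)
        gamma = rng.normal(size=(5, 3))
        beta = rng.normal(size=(5, 3))
        model.input_norm.gamma.data[:] = gamma
        model.input_norm.beta.data[:] = beta
        x = rng.normal(size=(32, 5, 3)) * 3 + 1
        out = model.input_norm(Tensor(x), training=True)
        mu, var = x.mean(axis=0), x.var(axis=0)
        oracle = gamma * (x - mu) / np.sqrt(var + 1e-5) + beta
        np.testing.assert_allclose(out.data, oracle, atol=1e-6)

    def test_batch_of_one_rejected_in_training(self):
        model = DAMGCNModel(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="eval mode or a larger batch"):
            model.input_norm(Tensor(np.zeros((1, 5, 3))), training=True)

    def test_eval_uses_running_stats(self, rng):
        model = DAMGCNModel(tiny_config(), seed=0)
        x = rng.normal(size=(64, 5, 3)) * 2 + 5
        for _ in range(50):
            model.input_norm(Tensor(x), training=True)
        out = model.input_norm(Tensor(x), training=False)
        assert abs(out.data.mean()) < 0.1


class TestGCNLayer:
    def test_identity_propagation_identity_weight(self, rng):
        model = DAMGCNModel(tiny_config(gcn_layers=1), seed=0)
        model.gcn_weights[0].data[:] = np.eye(3)
        x = rng.normal(size=(4, 5, 3))
        graph = ElectrodeGraph(montage=None, distances=np.zeros((5, 5)),
                               adjacency=np.eye(5), propagation=np.eye(5))
        out = model._gcn_block(Tensor(x), graph.propagation, training=False)
        # propagation = I, W = I: pre-activation is h + h = 2h, then GELU
        bn = model.input_norm(Tensor(x), training=False).data
        expected = 2 * bn * (1 / (1 + np.exp(-1.702 * 2 * bn)))
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_matches_brute_force_oracle(self, rng, tiny_graph):
        cfg = tiny_config(gcn_layers=2)
        model = DAMGCNModel(cfg, seed=3)
        x = rng.normal(size=(6, 5, 3))
        out = model._gcn_block(Tensor(x), tiny_graph.propagation, training=False)

        def gelu_np(v):
            return v / (1 + np.exp(-1.702 * v))

        h = model.input_norm(Tensor(x), training=False).data
        for w in model.gcn_weights:
            agg = np.einsum("ij,bjf,fg->big", tiny_graph.propagation, h, w.data)
            h = gelu_np(agg + h)
        np.testing.assert_allclose(out.data, h, atol=1e-6)

    def test_double_activation_flag(self, rng, tiny_graph):
        x = rng.normal(size=(4, 5, 3))
        single = DAMGCNModel(tiny_config(), seed=1)
        double = DAMGCNModel(tiny_config(double_activation=True), seed=1)
        o1 = single._gcn_block(Tensor(x), tiny_graph.propagation, False)
        o2 = double._gcn_block(Tensor(x), tiny_graph.propagation, False)
        assert not np.allclose(o1.data, o2.data)

    def test_constant_features_stay_constant_prew(self):
        # regular graph (equal distances): rows of the propagation matrix sum
        # equally, so a constant node vector stays constant under P @ H
        coords = np.array([[1.0, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                           [-0.5, -np.sqrt(3) / 2, 0]])
        g = build_graph(Montage(("a", "b", "c"), coords))
        h = np.full((3, 2), 3.7)
        out = g.propagation @ h
        np.testing.assert_allclose(out, np.broadcast_to(out[0], out.shape),
                                   atol=1e-12)


class TestAttention:
    def test_zero_qk_gives_uniform_rows(self, rng):
        model = DAMGCNModel(tiny_config(), seed=0)
        enc = model.channel_encoders[0]
        enc.wq.data[:] = 0.0
        enc.wk.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 5, 8)))
        _, attn = enc(x, training=False, rng=rng)
        np.testing.assert_allclose(attn, 1.0 / 5.0, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        model = DAMGCNModel(tiny_config(), seed=0)
        x = Tensor(rng.normal(size=(3, 5, 8)) * 5)
        _, attn = model.channel_encoders[0](x, training=False, rng=rng)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_head_hand_computation(self, rng):
        cfg = tiny_config(num_heads=1, embedding_size=2, num_channels=2,
                          num_bands=2)
        model = DAMGCNModel(cfg, seed=0)
        enc = model.channel_encoders[0]
        wq = np.array([[1.0, 0.0], [0.0, 1.0]])
        wk = np.array([[0.5, -0.5], [1.0, 0.0]])
        wv = np.array([[2.0, 0.0], [0.0, 2.0]])
        enc.wq.data[:], enc.wk.data[:], enc.wv.data[:] = wq, wk, wv
        x = np.array([[[1.0, 2.0], [-1.0, 0.5]]])  # (1, T=2, E=2)
        _, attn = enc(Tensor(x), training=False, rng=rng)
        # by-hand oracle: scores = (x wq)(x wk)^T / sqrt(2), row softmax
        q, k = x[0] @ wq, x[0] @ wk
        scores = q @ k.T / math.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        expected = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(attn[0, 0], expected, atol=1e-8)


class TestBandGate:
    def test_fresh_model_uniform_fifths(self):
        model = DAMGCNModel(ModelConfig(num_channels=4, num_bands=5,
                                        num_classes=2), seed=0)
        np.testing.assert_array_equal(model.band_gate_proportions(),
                                      np.full(5, 0.2))

    def test_hand_softmax(self):
        model = DAMGCNModel(ModelConfig(num_channels=4, num_bands=5,
                                        num_classes=2), seed=0)
        model.band_gate.data[:] = [math.log(2), 0, 0, 0, 0]
        p = model.band_gate_proportions()
        np.testing.assert_allclose(p, [2 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6])

    def test_random_gate_sums_to_one(self, rng):
        model = DAMGCNModel(ModelConfig(num_channels=4, num_bands=5,
                                        num_classes=2), seed=0)
        model.band_gate.data[:] = rng.normal(size=5) * 3
        assert model.band_gate_proportions().sum() == pytest.approx(1.0, abs=1e-12)

    def test_ablated_model_has_no_gate(self):
        model = DAMGCNModel(tiny_config(use_dam=False), seed=0)
        with pytest.raises(ValueError, match="use_dam"):
            model.band_gate_proportions()


class TestForward:
    def test_logit_shape_contract(self, rng):
        cfg = ModelConfig(num_channels=62, num_bands=5, num_classes=3)
        model = DAMGCNModel(cfg, seed=0)
        g = build_graph(Montage(tuple(f"c{i}" for i in range(62)),
                                rng.normal(size=(62, 3))))
        logits, trace = model.forward(rng.normal(size=(8, 62, 5)), g)
        assert logits.shape == (8, 3)
        assert trace.channel_attention.shape == (2, 6, 62, 62)
        assert trace.band_attention.shape == (2, 6, 5, 5)

    def test_linear_only_variant(self, rng):
        model = DAMGCNModel(tiny_config(use_gcn=False, use_dam=False), seed=0)
        logits, trace = model.forward(rng.normal(size=(4, 5, 3)))
        assert logits.shape == (4, 2)
        assert trace.channel_attention is None
        assert trace.band_gate_proportions is None
        # exactly two trainable linear maps plus biases
        assert len(model.parameters()) == 4

    def test_ablation_variants_differ(self, rng, tiny_graph):
        x = rng.normal(size=(4, 5, 3))
        outs = []
        for flags in [(True, True), (True, False), (False, True), (False, False)]:
            m = DAMGCNModel(tiny_config(use_gcn=flags[0], use_dam=flags[1]), seed=0)
            logits, _ = m.forward(x, tiny_graph if flags[0] else None)
            outs.append(logits.data)
        for i in range(len(outs)):
            for j in range(i + 1, len(outs)):
                assert not np.allclose(outs[i], outs[j])

    def test_deterministic_given_seed(self, rng, tiny_graph):
        x = rng.normal(size=(4, 5, 3))
        cfg = tiny_config(dropout=0.5)
        a = DAMGCNModel(cfg, seed=9).forward(
            x, tiny_graph, training=True, rng=np.random.default_rng(5))[0].data
        b = DAMGCNModel(cfg, seed=9).forward(
            x, tiny_graph, training=True, rng=np.random.default_rng(5))[0].data
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self, rng, tiny_graph):
        model = DAMGCNModel(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.forward(rng.normal(size=(4, 6, 3)), tiny_graph)

    def test_gcn_requires_graph(self, rng):
        model = DAMGCNModel(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="graph"):
            model.forward(rng.normal(size=(4, 5, 3)), None)

    def test_attention_rows_and_gate_simplex(self, rng, tiny_graph):
        model = DAMGCNModel(tiny_config(), seed=0)
        _, trace = model.forward(rng.normal(size=(6, 5, 3)), tiny_graph)
        np.testing.assert_allclose(trace.channel_attention.sum(axis=-1), 1.0,
                                   atol=1e-6)
        np.testing.assert_allclose(trace.band_attention.sum(axis=-1), 1.0,
                                   atol=1e-6)
        assert trace.band_gate_proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(trace.band_gate_proportions >= 0)


class TestPermutationEquivariance:
    def test_gcn_block_equivariant(self, rng):
        # permuting channels of input and graph together permutes output rows
        cfg = tiny_config()
        coords = rng.normal(size=(5, 3))
        g = build_graph(Montage(tuple("abcde"), coords))
        perm = np.array([3, 0, 4, 1, 2])
        g_p = build_graph(Montage(tuple(np.array(list("abcde"))[perm]),
                                  coords[perm]))
        x = rng.normal(size=(6, 5, 3))

        m1 = DAMGCNModel(cfg, seed=2)
        m2 = DAMGCNModel(cfg, seed=2)
        # batch-norm parameters are per-channel: permute them consistently
        for attr in ("gamma", "beta"):
            getattr(m2.input_norm, attr).data[:] = getattr(
                m1.input_norm, attr).data[perm]
        m2.input_norm.running_mean = m1.input_norm.running_mean[perm]
        m2.input_norm.running_var = m1.input_norm.running_var[perm]

        out1 = m1._gcn_block(Tensor(x), g.propagation, training=False).data
        out2 = m2._gcn_block(Tensor(x[:, perm]), g_p.propagation,
                             training=False).data
        np.testing.assert_allclose(out2, out1[:, perm], atol=1e-10)


class TestLoss:
    def test_argmax_prediction(self):
        assert predict(np.array([[10.0, 0.0, 0.0]]))[0] == 0

    def test_uniform_logits_log_k(self):
        logits = Tensor(np.zeros((7, 3)))
        loss = cross_entropy(logits, np.array([0, 1, 2, 0, 1, 2, 0]))
        assert loss.data == pytest.approx(math.log(3.0), abs=1e-12)

    def test_matches_scalar_oracle(self, rng):
        logits = rng.normal(size=(10, 4)) * 3
        labels = rng.integers(0, 4, size=10)
        loss = cross_entropy(Tensor(logits), labels)
        # by-hand softmax + log
        total = 0.0
        for i in range(10):
            p = np.exp(logits[i]) / np.exp(logits[i]).sum()
            total -= math.log(p[labels[i]])
        assert loss.data == pytest.approx(total / 10, abs=1e-6)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="labels"):
            cross_entropy(Tensor(np.zeros((2, 3))), np.array([0, 3]))


class TestGradientCheck:
    def test_full_model_numeric_gradient(self, rng, tiny_graph):
        """Finite-difference check of a sampled parameter subset (<= 1e-4)."""
        model = DAMGCNModel(tiny_config(), seed=1)
        x = rng.normal(size=(6, 5, 3))
        y = rng.integers(0, 2, size=6)

        def loss_value():
            logits, _ = model.forward(x, tiny_graph, training=True,
                                      rng=np.random.default_rng(0))
            return cross_entropy(logits, y)

        loss = loss_value()
        loss.backward()
        params = model.parameters()
        prng = np.random.default_rng(0)
        checked = 0
        while checked < 20:
            p = params[prng.integers(len(params))]
            if p.grad is None:
                continue
            flat = prng.integers(p.data.size)
            eps = 1e-6
            orig = p.data.flat[flat]
            p.data.flat[flat] = orig + eps
            lp = loss_value().data
            p.data.flat[flat] = orig - eps
            lm = loss_value().data
            p.data.flat[flat] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.flat[flat]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), (num, ana)
            checked += 1


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng, tiny_graph):
        model = DAMGCNModel(tiny_config(), seed=4)
        x = rng.normal(size=(3, 5, 3))
        before = model.forward(x, tiny_graph)[0].data
        path = tmp_path / "model.ckpt"
        save_model(model, path)
        restored = load_model(path)
        after = restored.forward(x, tiny_graph)[0].data
        np.testing.assert_array_equal(before, after)

    def test_config_preserved(self, tmp_path):
        cfg = tiny_config(use_gcn=False)
        save_model(DAMGCNModel(cfg, seed=0), tmp_path / "m.ckpt")
        assert load_model(tmp_path / "m.ckpt").config == cfg
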