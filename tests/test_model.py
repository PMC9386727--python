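"""Architecture: global attention vs brute-force oracle, shapes, parameter
ledger, receptive fields, determinism."""

import math

import numpy as np
import pytest
from scipy.special import erf

from proteinlm import ModelConfig, build_model, conv_receptive_field, count_parameters
from proteinlm.autodiff import Tensor
from proteinlm.layers import Conv1d
from proteinlm.model import GlobalAttentionHead


def reference_gelu(v):
    return v * 0.5 * (1.0 + erf(v / math.sqrt(2.0)))


def brute_force_attention(x, s, Wq, Wk, Wv, d_key):
    """Independent double-loop transcription of the attention formulas."""
    L = len(s)
    q = np.tanh(Wq @ x)
    scores = np.array([float(q @ np.tanh(Wk @ s[i])) / math.sqrt(d_key)
                       for i in range(L)])
    e = np.exp(scores - scores.max())
    z = e / e.sum()
    y = sum(z[i] * reference_gelu(Wv @ s[i]) for i in range(L))
    return y, z


class TestGlobalAttention:
    def _head(self, cfg, seed):
        return GlobalAttentionHead(cfg, np.random.default_rng(seed))

    def test_matches_brute_force_oracle_on_100_random_instances(self):
        """Vectorized head vs explicit-formula loop, 1e-10 agreement."""
        rng = np.random.default_rng(2024)
        for trial in range(100):
            dl, dg, dk = rng.integers(1, 6, 3)
            heads = int(rng.integers(1, 4))
            dg = int(dg) * heads  # keep d_global divisible by n_heads
            L = int(rng.integers(1, 8))
            cfg = ModelConfig(d_local=int(dl), d_global=dg, n_blocks=1,
                              n_heads=heads, d_key=int(dk), n_annotations=2)
            head = self._head(cfg, trial)
            x = rng.normal(size=(1, dg))
            s = rng.normal(size=(1, L, int(dl)))
            y, z = head(Tensor(x), Tensor(s), return_weights=True)
            y_ref, z_ref = brute_force_attention(
                x[0], s[0], head.Wq.data, head.Wk.data, head.Wv.data, int(dk))
            np.testing.assert_allclose(y.data[0], y_ref, atol=1e-10)
            np.testing.assert_allclose(z.data[0], z_ref, atol=1e-10)

    def test_single_position_gets_all_attention(self, tiny_config, rng):
        head = self._head(tiny_config, 0)
        s = Tensor(rng.normal(size=(1, 1, tiny_config.d_local)))
        x = Tensor(rng.normal(size=(1, tiny_config.d_global)))
        y, z = head(x, s, return_weights=True)
        assert z.data[0].tolist() == [1.0]
        expected = reference_gelu(head.Wv.data @ s.data[0, 0])
        np.testing.assert_allclose(y.data[0], expected, atol=1e-12)

    def test_identical_positions_share_attention_equally(self, tiny_config, rng):
        head = self._head(tiny_config, 1)
        one = rng.normal(size=(1, 1, tiny_config.d_local))
        s = Tensor(np.repeat(one, 7, axis=1))
        x = Tensor(rng.normal(size=(1, tiny_config.d_global)))
        _, z = head(x, s, return_weights=True)
        np.testing.assert_allclose(z.data[0], np.full(7, 1 / 7), atol=1e-12)

    def test_weights_sum_to_one_and_output_is_permutation_invariant(self, tiny_config, rng):
        head = self._head(tiny_config, 2)
        s = rng.normal(size=(1, 11, tiny_config.d_local))
        x = Tensor(rng.normal(size=(1, tiny_config.d_global)))
        y, z = head(x, Tensor(s), return_weights=True)
        assert z.data.sum() == pytest.approx(1.0, abs=1e-6)
        perm = rng.permutation(11)
        y_p, _ = head(x, Tensor(s[:, perm]), return_weights=True)
        np.testing.assert_allclose(y.data, y_p.data, atol=1e-12)

    def test_empty_sequence_raises(self, tiny_config, rng):
        head = self._head(tiny_config, 3)
        with pytest.raises(ValueError):
            head(Tensor(rng.normal(size=(1, tiny_config.d_global))),
                 Tensor(np.zeros((1, 0, tiny_config.d_local))))

    def test_multihead_concatenates_heads_in_order(self, tiny_config, rng):
        model = build_model(tiny_config, rng=5)
        att = model.blocks[0].attention
        x = Tensor(rng.normal(size=(2, tiny_config.d_global)))
        s = Tensor(rng.normal(size=(2, 9, tiny_config.d_local)))
        out = att(x, s)
        assert out.shape == (2, tiny_config.n_heads * tiny_config.d_value)
        dv = tiny_config.d_value
        for h, head in enumerate(att.heads):
            np.testing.assert_allclose(out.data[:, h * dv:(h + 1) * dv],
                                       head(x, s).data, atol=1e-12)


class TestModelConfig:
    def test_default_head_dimensions(self):
        cfg = ModelConfig()
        assert cfg.d_value == 128
        assert cfg.n_heads * cfg.d_value == cfg.d_global == 512

    @pytest.mark.parametrize("bad", [
        {"d_global": 510},            # not divisible by n_heads
        {"conv_kernel": 8},           # even kernel
        {"n_blocks": 0},
        {"n_annotations": -1},
    ])
    def test_invalid_configs_rejected_with_named_violation(self, bad):
        with pytest.raises(ValueError, match="invalid model config"):
            ModelConfig(**bad)


def toy_parameter_ledger(cfg: ModelConfig) -> int:
    """Hand-enumerated parameter shapes, kept independent of the model code."""
    dl, dg, k = cfg.d_local, cfg.d_global, cfg.conv_kernel
    dv = cfg.d_global // cfg.n_heads
    n = cfg.vocab_size * dl                       # token embedding
    n += cfg.n_annotations * dg + dg              # annotation input dense
    per_block = (
        (k * dl * dl + dl) * 2                    # narrow + wide conv
        + (2 * dl) * dl + dl                      # concat-reduce dense
        + 2 * dl                                  # LN after conv sub-block
        + dg * dl + dl                            # broadcast dense
        + 2 * dl                                  # LN after broadcast
        + cfg.n_heads * (cfg.d_key * dg + cfg.d_key * dl + dv * dl)  # attention
        + 2 * dg                                  # LN after attention
        + (dg * dg + dg) * 2                      # two global dense layers
        + 2 * dg                                  # LN after global dense
    )
    n += cfg.n_blocks * per_block
    n += dl * cfg.vocab_size + cfg.vocab_size     # sequence head
    n += dg * cfg.n_annotations + cfg.n_annotations  # annotation head
    return n


class TestParameterCount:
    def test_toy_config_matches_hand_ledger_exactly(self):
        cfg = ModelConfig(d_local=4, d_global=8, n_blocks=1, n_heads=2,
                          d_key=3, n_annotations=5)
        model = build_model(cfg, rng=0)
        assert count_parameters(model) == toy_parameter_ledger(cfg)

    def test_tiny_config_matches_hand_ledger_exactly(self, tiny_config):
        model = build_model(tiny_config, rng=0)
        assert count_parameters(model) == toy_parameter_ledger(tiny_config)

    def test_count_stable_across_forward_passes(self, tiny_config, rng):
        model = build_model(tiny_config, rng=0)
        before = count_parameters(model)
        model.forward(rng.integers(0, 26, (2, 10)),
                      rng.integers(0, 2, (2, tiny_config.n_annotations)))
        assert count_parameters(model) == before

    def test_no_positional_embedding_in_parameter_ledger(self, tiny_config):
        model = build_model(tiny_config, rng=0)
        names = list(model.named_parameters())
        assert names, "model must expose named parameters"
        assert not any("pos" in name.lower() for name in names)


class TestReceptiveField:
    def test_analytic_values_for_default_config(self):
        assert conv_receptive_field(ModelConfig()) == (9, 41, 241)

    @pytest.mark.parametrize("dilation,expected", [(1, 9), (2, 17), (5, 41)])
    def test_single_conv_probe_agrees_with_formula(self, dilation, expected, rng):
        conv = Conv1d(3, 3, kernel=9, dilation=dilation, rng=rng)
        L = 120
        x = rng.normal(size=(1, L, 3))
        base = conv(Tensor(x)).data
        x2 = x.copy()
        x2[0, L // 2] += 1.0
        diff = np.abs(conv(Tensor(x2)).data - base).max(-1)[0]
        span = np.where(diff > 1e-12)[0]
        assert span[-1] - span[0] + 1 == expected

    def test_block_stack_probe_matches_total_with_coupling_disabled(self, rng):
        """Perturb one input token with broadcast layers zeroed; the local
        output may change only inside the analytic total receptive field."""
        cfg = ModelConfig(d_local=6, d_global=8, n_blocks=3, n_heads=2,
                          d_key=3, n_annotations=2)
        _, _, total = conv_receptive_field(cfg)
        model = build_model(cfg, rng=8)
        model.zero_global_coupling()
        L = total + 40
        tok = rng.integers(0, 20, (1, L))
        ann = np.zeros((1, 2))
        base, _ = model.hidden_states(tok, ann)
        tok2 = tok.copy()
        center = L // 2
        tok2[0, center] = (tok2[0, center] + 1) % 20
        pert, _ = model.hidden_states(tok2, ann)
        diff = np.abs(base.data - pert.data).max(-1)[0]
        span = np.where(diff > 1e-12)[0]
        assert span.min() == center - (total - 1) // 2
        assert span.max() == center + (total - 1) // 2


class TestModelForward:
    @pytest.mark.parametrize("L", [8, 128, 700])
    def test_shapes_preserved_for_any_length(self, tiny_config, rng, L):
        model = build_model(tiny_config, rng=0)
        out = model.forward(rng.integers(0, 26, (2, L)),
                            rng.integers(0, 2, (2, tiny_config.n_annotations)))
        assert out.token_probs.shape == (2, L, 26)
        assert out.annotation_probs.shape == (2, tiny_config.n_annotations)
        np.testing.assert_allclose(out.token_probs.data.sum(-1), 1.0, atol=1e-5)
        assert ((out.annotation_probs.data >= 0) & (out.annotation_probs.data <= 1)).all()

    def test_global_output_ignores_sequence_when_coupling_zeroed(self, tiny_config, rng):
        model = build_model(tiny_config, rng=1)
        for block in model.blocks:
            for head in block.attention.heads:
                head.Wv.data[:] = 0.0
        ann = rng.integers(0, 2, (1, tiny_config.n_annotations))
        out_a = model.forward(rng.integers(0, 26, (1, 30)), ann)
        out_b = model.forward(rng.integers(0, 26, (1, 30)), ann)
        np.testing.assert_allclose(out_a.annotation_probs.data,
                                   out_b.annotation_probs.data, atol=1e-12)

    def test_same_seed_builds_bit_identical_models(self, tiny_config):
        a = build_model(tiny_config, rng=42)
        b = build_model(tiny_config, rng=42)
        for (na, pa), (nb, pb) in zip(a.named_parameters().items(),
                                      b.named_parameters().items()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)

    def test_out_of_range_token_and_bad_annotation_shape_raise(self, tiny_config, rng):
        model = build_model(tiny_config, rng=0)
        with pytest.raises(ValueError):
            model.forward(np.array([[99]]), np.zeros((1, tiny_config.n_annotations)))
        with pytest.raises(ValueError):
            model.forward(rng.integers(0, 26, (1, 5)), np.zeros((1, 3)))
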