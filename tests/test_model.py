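"""Tests of the masked co-binding model: embedding arithmetic, attention,
decoder shape, masking statistics, focal loss, schedule, and the training loop."""

import numpy as np
import pytest

from cobindlm import nn
from cobindlm.model import (
    CoBindingModel,
    MaskingConfig,
    ModelConfig,
    TrainConfig,
    apply_masking,
    focal_loss,
    lr_schedule,
    pretrain,
)
from cobindlm.nn import Tensor


@pytest.fixture(scope="module")
def tiny_model():
    return CoBindingModel(ModelConfig(seq_len=4, d_model=8, n_blocks=2,
                                      n_heads=2, ff_mult=2), seed=0)


class TestEmbedInput:
    def test_zero_tables_give_zero_embeddings(self, tiny_model):
        model = CoBindingModel(tiny_model.config, seed=1)
        model.token_table.weight.data[:] = 0
        model.position_table.weight.data[:] = 0
        out = model.embed_input(np.array([0, 1, 2, 3]))
        np.testing.assert_array_equal(out.data, 0)

    def test_additivity_of_position_and_token_rows(self, tiny_model):
        out = tiny_model.embed_input(np.array([2, 2, 0, 5]))
        pos = tiny_model.position_table.weight.data
        diff = out.data[1] - out.data[0]          # same token, different position
        np.testing.assert_allclose(diff, pos[1] - pos[0], atol=1e-7)

    def test_rows_match_hand_added_table_rows(self, tiny_model):
        tokens = np.array([1, 4, 3, 0])
        out = tiny_model.embed_input(tokens)
        tok = tiny_model.token_table.weight.data
        pos = tiny_model.position_table.weight.data
        np.testing.assert_allclose(out.data[2], pos[2] + tok[3], atol=1e-7)

    def test_out_of_vocabulary_token_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="vocabulary"):
            tiny_model.embed_input(np.array([0, 1, 2, 6]))


class TestEncoder:
    def test_zero_blocks_is_identity(self):
        model = CoBindingModel(ModelConfig(seq_len=4, d_model=8, n_blocks=0,
                                           n_heads=2), seed=0)
        emb = model.embed_input(np.array([0, 1, 2, 3]))
        np.testing.assert_array_equal(model.encode(emb).data, emb.data)

    def test_single_head_attention_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        attn = nn.MultiHeadSelfAttention(3, 1, rng)
        x = rng.normal(size=(2, 3)).astype(np.float32)
        out = attn(Tensor(x)).data
        # by hand: Q K V projections, scores / sqrt(d), softmax, context, output
        q = x @ attn.w_q.weight.data + attn.w_q.bias.data
        k = x @ attn.w_k.weight.data + attn.w_k.bias.data
        v = x @ attn.w_v.weight.data + attn.w_v.bias.data
        s = q @ k.T / np.sqrt(3)
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        expected = (a @ v) @ attn.w_o.weight.data + attn.w_o.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_literal_scaling_mode_divides_by_model_dim(self):
        rng = np.random.default_rng(0)
        attn = nn.MultiHeadSelfAttention(4, 2, rng, scaling="model_dim")
        assert attn.scale == pytest.approx(1 / 4)
        per_head = nn.MultiHeadSelfAttention(4, 2, rng, scaling="per_head")
        assert per_head.scale == pytest.approx(1 / np.sqrt(2))

    def test_width_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="d_model"):
            tiny_model.encode(Tensor(np.zeros((4, 5), dtype=np.float32)))


class TestDecoder:
    def test_zero_weights_give_uniform_softmax(self, tiny_model):
        model = CoBindingModel(tiny_model.config, seed=2)
        for p in (model.dec1.weight, model.dec1.bias, model.dec2.weight,
                  model.dec2.bias):
            p.data[:] = 0
        logits = model.decode_logits(Tensor(np.ones((4, 8), dtype=np.float32)))
        np.testing.assert_array_equal(logits.data, 0)
        np.testing.assert_allclose(logits.softmax(-1).data, 0.2)

    def test_output_width_is_five_statuses(self, tiny_model):
        logits = tiny_model.decode_logits(Tensor(np.zeros((7, 4, 8), dtype=np.float32)))
        assert logits.shape == (7, 4, 5)


class TestMasking:
    def test_zero_select_rate_is_identity(self, rng):
        tokens = rng.integers(0, 5, size=(3, 10))
        cfg = MaskingConfig(select_rate=0.0)
        corrupted, selected, _ = apply_masking(tokens, cfg, rng)
        np.testing.assert_array_equal(corrupted, tokens)
        assert not selected.any()

    def test_full_masking_replaces_everything(self, rng):
        tokens = rng.integers(0, 5, size=(3, 10))
        cfg = MaskingConfig(select_rate=1.0, mask_rate=1.0, random_rate=0.0,
                            keep_rate=0.0)
        corrupted, selected, labels = apply_masking(tokens, cfg, rng)
        assert (corrupted == cfg.mask_token_id).all()
        assert selected.all()
        np.testing.assert_array_equal(labels, tokens)

    def test_selection_and_mask_fractions_concentrate(self, rng):
        tokens = rng.integers(0, 5, size=10**6)
        corrupted, selected, _ = apply_masking(tokens, MaskingConfig(), rng)
        assert abs(selected.mean() - 0.15) < 0.002
        frac_mask = (corrupted[selected] == MaskingConfig().mask_token_id).mean()
        assert abs(frac_mask - 0.8) < 0.005

    def test_rates_must_sum_to_one(self):
        with pytest.raises(ValueError, match="must equal 1"):
            MaskingConfig(mask_rate=0.8, random_rate=0.3, keep_rate=0.1)


class TestFocalLoss:
    def test_perfect_prediction_gives_zero_loss(self):
        probs = np.zeros((4, 5))
        labels = np.array([0, 3, 1, 4])
        probs[np.arange(4), labels] = 1.0
        loss = focal_loss(Tensor(probs), labels, np.ones(4, bool), gamma=2.0)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_hand_value(self):
        # one selected position, p_true = 0.5, gamma 2: 0.25 * ln 2 = 0.173287
        probs = np.full((1, 5), 0.125)
        probs[0, 2] = 0.5
        loss = focal_loss(Tensor(probs), np.array([2]), np.array([True]), gamma=2.0)
        assert float(loss.data) == pytest.approx(0.25 * np.log(2), abs=1e-6)
        assert float(loss.data) == pytest.approx(0.173287, abs=1e-6)

    def test_gamma_zero_equals_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(5), size=8)
        labels = rng.integers(0, 5, size=8)
        selected = rng.random(8) < 0.6
        loss = focal_loss(Tensor(probs), labels, selected, gamma=0.0)
        ce = -np.log(probs[np.arange(8), labels])[selected].sum()
        assert float(loss.data) == pytest.approx(ce, abs=1e-9)

    def test_unselected_positions_have_zero_gradient(self, rng):
        logits = Tensor(rng.normal(size=(2, 6, 5)), requires_grad=True)
        labels = rng.integers(0, 5, size=(2, 6))
        selected = np.zeros((2, 6), bool)
        selected[0, 1] = selected[1, 4] = True
        focal_loss(logits.softmax(-1), labels, selected, gamma=2.0).backward()
        assert np.abs(logits.grad[~selected]).max() == 0
        assert np.abs(logits.grad[selected]).max() > 0

    def test_loss_nonnegative(self, rng):
        probs = rng.dirichlet(np.ones(5), size=(3, 4))
        labels = rng.integers(0, 5, size=(3, 4))
        selected = rng.random((3, 4)) < 0.5
        loss = focal_loss(Tensor(probs), labels, selected, gamma=2.0)
        assert float(loss.data) >= 0


class TestSchedule:
    def test_starts_at_zero(self):
        assert lr_schedule(0, 1000, TrainConfig()) == 0.0

    def test_peak_at_end_of_warmup(self):
        assert lr_schedule(100, 1000, TrainConfig()) == pytest.approx(1e-4)

    def test_decay_midpoint(self):
        assert lr_schedule(550, 1000, TrainConfig()) == pytest.approx(5e-5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(1001, 1000, TrainConfig())


class TestPretrainLoop:
    def test_loss_history_counts_optimizer_steps(self, rng):
        tokens = rng.integers(0, 5, size=(10, 6))
        cfg = ModelConfig(seq_len=6, d_model=8, n_blocks=1, n_heads=2, ff_mult=1)
        train = TrainConfig(max_lr=1e-3, batch_size=4, grad_accumulation=1,
                            epochs=1, seed=0)
        _, history = pretrain(tokens, cfg, MaskingConfig(), train)
        assert len(history) == int(np.ceil(10 / 4))

    def test_gradient_accumulation_reduces_step_count(self, rng):
        tokens = rng.integers(0, 5, size=(16, 6))
        cfg = ModelConfig(seq_len=6, d_model=8, n_blocks=1, n_heads=2, ff_mult=1)
        train = TrainConfig(max_lr=1e-3, batch_size=4, grad_accumulation=2,
                            epochs=1, seed=0)
        _, history = pretrain(tokens, cfg, MaskingConfig(), train)
        assert len(history) == 2

    def test_determinism_under_fixed_seed(self, rng):
        tokens = rng.integers(0, 5, size=(12, 6))
        cfg = ModelConfig(seq_len=6, d_model=8, n_blocks=1, n_heads=2, ff_mult=1)
        train = TrainConfig(max_lr=1e-3, batch_size=4, grad_accumulation=1,
                            epochs=2, seed=5)
        m1, h1 = pretrain(tokens, cfg, MaskingConfig(), train)
        m2, h2 = pretrain(tokens, cfg, MaskingConfig(), train)
        assert h1 == h2
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pretrain(np.empty((0, 4), dtype=int))


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "ckpt.npz"
        tiny_model.save(path)
        loaded = CoBindingModel.load(path)
        assert loaded.config == tiny_model.config
        for a, b in zip(tiny_model.state_arrays(), loaded.state_arrays()):
            np.testing.assert_array_equal(a, b)
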