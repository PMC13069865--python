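"""Tests of selective freezing, the universal head, gene pooling, prompts,
and the fine-tuning loop on planted-driver data."""

import hashlib

import numpy as np
import pytest

from cobindlm.encoding import encode_matrix
from cobindlm.finetune import (
    FreezePolicy,
    PromptVector,
    RegionHead,
    TaskSpec,
    concat_prompt,
    finetune_task,
    freeze,
    gene_pool,
    make_gene_windows,
)
from cobindlm.model import (
    CoBindingModel,
    MaskingConfig,
    ModelConfig,
    TrainConfig,
    pretrain,
)
from cobindlm.nn import Linear, Tensor
from cobindlm.synthetic import (
    SyntheticConfig,
    generate_catalog,
    generate_celltype_pair,
    generate_region_labels,
    generate_signal_matrix,
)


def _hash(arrays):
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


@pytest.fixture(scope="module")
def driver_world():
    cfg = SyntheticConfig(n_regulators=16, cistromes_per_regulator=1,
                          n_modules=4, n_regions=1200, label_noise_sd=0.0,
                          n_drivers=3, seed=5)
    catalog, truth = generate_catalog(cfg)
    matrix, peaks = generate_signal_matrix(catalog, truth, cfg)
    tokens = encode_matrix(matrix)
    labels = generate_region_labels(truth, peaks, "binary", cfg, catalog)
    mc = ModelConfig(seq_len=16, d_model=32, n_blocks=2, n_heads=4, ff_mult=2)
    model, _ = pretrain(tokens.tokens, mc, MaskingConfig(),
                        TrainConfig(max_lr=1e-3, batch_size=32,
                                    grad_accumulation=1, epochs=2, seed=0))
    return {"config": cfg, "catalog": catalog, "truth": truth,
            "tokens": tokens, "labels": labels, "model_config": mc,
            "state": [a.copy() for a in model.state_arrays()]}


def _fresh_model(world):
    model = CoBindingModel(world["model_config"], seed=0)
    model.load_arrays(world["state"])
    return model


class TestFreeze:
    def test_out_of_range_policy_rejected(self, driver_world):
        model = _fresh_model(driver_world)
        with pytest.raises(ValueError):
            freeze(model, FreezePolicy(n_trainable_final_blocks=3))

    @pytest.mark.parametrize("n_final", [0, 1, 2])
    def test_exactly_the_intended_parameters_change(self, driver_world, n_final):
        world = driver_world
        model = _fresh_model(world)
        freeze(model, FreezePolicy(n_trainable_final_blocks=n_final))
        frozen = [p for p in model.parameters() if not p.requires_grad]
        trainable = model.trainable_parameters()
        assert len(trainable) == sum(
            len(b.parameters())
            for b in model.blocks[len(model.blocks) - n_final:])
        before = _hash([p.data for p in frozen])
        ds = {"tokens": world["tokens"].tokens, "labels": world["labels"],
              "catalog": world["catalog"]}
        finetune_task(model, ds, TaskSpec(), FreezePolicy(n_final),
                      TrainConfig(max_lr=3e-3, batch_size=64,
                                  grad_accumulation=1, epochs=1, seed=0))
        assert _hash([p.data for p in frozen]) == before
        assert model.token_table.weight.requires_grad is False


class TestGenePool:
    def test_identical_bins_are_identity(self, rng):
        w = np.tile(rng.normal(size=(1, 2, 3)), (9, 1, 1))
        np.testing.assert_array_equal(gene_pool(w), w[0])

    def test_dominating_bin_is_returned(self, rng):
        w = rng.normal(size=(9, 2, 3))
        w[4] = 100.0
        np.testing.assert_array_equal(gene_pool(w), w[4])

    def test_matches_elementwise_max_oracle(self, rng):
        w = rng.normal(size=(9, 2, 3))
        np.testing.assert_array_equal(gene_pool(w), w.max(axis=0))
        t = gene_pool(Tensor(w))
        np.testing.assert_array_equal(t.data, w.max(axis=0))

    def test_wrong_window_size_rejected(self, rng):
        with pytest.raises(ValueError, match="9 bins"):
            gene_pool(rng.normal(size=(7, 2, 3)))

    def test_edge_windows_error_unless_padded(self):
        with pytest.raises(ValueError, match="edge"):
            make_gene_windows(100, np.array([2]))
        w = make_gene_windows(100, np.array([2]), pad_edges=True)
        assert w.min() == 0 and w.shape == (1, 9)


class TestConcatPrompt:
    def test_matching_width_concatenates_directly(self, rng):
        emb = Tensor(rng.normal(size=(5, 4)))
        out = concat_prompt(emb, PromptVector(rng.normal(size=4)))
        assert out.shape == (5, 8)

    def test_mismatched_width_requires_projection(self, rng):
        emb = Tensor(rng.normal(size=(5, 4)))
        prompt = PromptVector(rng.normal(size=12))
        with pytest.raises(ValueError, match="projection"):
            concat_prompt(emb, prompt)
        proj = Linear(12, 4, rng)
        out = concat_prompt(emb, prompt, proj)
        assert out.shape == (5, 8)

    def test_zero_prompt_zeroes_second_half(self, rng):
        emb = Tensor(rng.normal(size=(3, 4)))
        out = concat_prompt(emb, PromptVector(np.zeros(4)))
        np.testing.assert_array_equal(out.data[:, 4:], 0.0)
        np.testing.assert_array_equal(out.data[:, :4], emb.data)


class TestRegionHead:
    def test_zero_weights_give_zero_output(self, rng):
        head = RegionHead(4, seed=0)
        for p in head.parameters():
            p.data[:] = 0
        out = head(Tensor(rng.normal(size=(7, 3, 4))))
        np.testing.assert_array_equal(out.data, 0.0)   # sigmoid -> 0.5

    def test_single_scalar_per_region_for_any_regulator_count(self, rng):
        head = RegionHead(4, seed=0)
        for m in (1, 5, 11):
            out = head(Tensor(rng.normal(size=(3, m, 4))))
            assert out.shape == (3,)

    def test_matches_manual_toy_computation(self):
        head = RegionHead(2, hidden=2, seed=1)
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        out = head(Tensor(x)).data
        h1 = np.maximum(x @ head.conv.weight.data + head.conv.bias.data, 0)
        pooled = h1.mean(axis=1)
        h2 = np.maximum(pooled @ head.fc1.weight.data + head.fc1.bias.data, 0)
        expected = (h2 @ head.fc2.weight.data + head.fc2.bias.data)[:, 0]
        np.testing.assert_allclose(out, expected, rtol=1e-6)


class TestFinetuneTask:
    def test_noiseless_driver_task_reaches_high_auroc(self, driver_world):
        world = driver_world
        model = _fresh_model(world)
        ds = {"tokens": world["tokens"].tokens, "labels": world["labels"],
              "catalog": world["catalog"]}
        _, _, metrics = finetune_task(
            model, ds, TaskSpec(), FreezePolicy(2),
            TrainConfig(max_lr=3e-3, batch_size=32, grad_accumulation=1,
                        epochs=15, seed=0))
        assert metrics["auroc"] >= 0.95

    def test_degenerate_single_class_labels_abort(self, driver_world):
        world = driver_world
        model = _fresh_model(world)
        ds = {"tokens": world["tokens"].tokens,
              "labels": np.ones_like(world["labels"]),
              "catalog": world["catalog"]}
        with pytest.raises(ValueError, match="single-class"):
            finetune_task(model, ds, TaskSpec(), FreezePolicy(1),
                          TrainConfig(max_lr=1e-3, batch_size=32,
                                      grad_accumulation=1, epochs=1, seed=0))

    def test_constant_regression_labels_flagged(self, driver_world):
        world = driver_world
        model = _fresh_model(world)
        ds = {"tokens": world["tokens"].tokens,
              "labels": np.full(world["labels"].shape, 2.5),
              "catalog": world["catalog"]}
        _, _, metrics = finetune_task(
            model, ds, TaskSpec(objective="regression", loss="mse"),
            FreezePolicy(0),
            TrainConfig(max_lr=1e-3, batch_size=64, grad_accumulation=1,
                        epochs=1, seed=0))
        assert "constant_labels" in metrics["flags"]
        assert np.isnan(metrics["r2"])


@pytest.fixture(scope="module")
def imputation_world():
    cfg = SyntheticConfig(n_regulators=16, cistromes_per_regulator=1,
                          n_modules=4, n_regions=1500, n_drivers=2, seed=9)
    target = "TF01"
    pair = generate_celltype_pair(cfg, {"TF01", "TF05"}, n_delta_regions=400)
    tokens = encode_matrix(pair.matrix_a)
    cols = pair.catalog.columns_of(target)
    labels = (pair.peaks_b.bound_mask[:, cols].mean(axis=1) > 0.5).astype(int)
    # per-region accessibility summary of the target cell state
    occ_b = pair.peaks_b.bound_mask.mean(axis=1, keepdims=True)
    occ_a = pair.peaks_a.bound_mask.mean(axis=1, keepdims=True)
    noise = np.random.default_rng(0).normal(0, 0.1, size=(cfg.n_regions, 3))
    prompt = np.hstack([occ_b, occ_a, occ_b - occ_a, noise])
    mc = ModelConfig(seq_len=16, d_model=32, n_blocks=2, n_heads=4, ff_mult=2)
    model, _ = pretrain(tokens.tokens, mc, MaskingConfig(),
                        TrainConfig(max_lr=1e-3, batch_size=32,
                                    grad_accumulation=1, epochs=2, seed=0))
    return {"pair": pair, "tokens": tokens, "labels": labels,
            "prompt": prompt, "target": target, "model_config": mc,
            "state": [a.copy() for a in model.state_arrays()]}


class TestImputationWithPrompts:
    def _run(self, world, prompt_values, seed):
        model = CoBindingModel(world["model_config"], seed=0)
        model.load_arrays(world["state"])
        ds = {"tokens": world["tokens"].tokens, "labels": world["labels"],
              "catalog": world["pair"].catalog,
              "prompt": PromptVector(prompt_values)}
        _, _, metrics = finetune_task(
            model, ds, TaskSpec(loss="bce"), FreezePolicy(1),
            TrainConfig(max_lr=3e-3, batch_size=32, grad_accumulation=1,
                        epochs=8, seed=seed),
            target_regulator=world["target"])
        return metrics["auprc"]

    def test_prompted_imputation_beats_prevalence_by_wide_margin(
            self, imputation_world):
        auprc = self._run(imputation_world, imputation_world["prompt"], seed=0)
        prevalence = imputation_world["labels"].mean()
        assert auprc >= prevalence + 0.2

    def test_prompt_ablation_sign_test_over_five_seeds(self, imputation_world):
        world = imputation_world
        zero = np.zeros_like(world["prompt"])
        wins = sum(self._run(world, world["prompt"], seed=s)
                   > self._run(world, zero, seed=s) for s in range(5))
        # one-sided sign test: 5/5 wins gives p = 2^-5 ~ 0.031 < 0.05
        assert wins == 5
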