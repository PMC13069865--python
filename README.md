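# cobindlm

Masked language modeling of transcription-regulator co-binding, for
regulatory genomics at desk scale.

Genome-wide binding maps (cistromes) from ChIP-seq, DNase-seq and ATAC-seq
show that transcription regulators bind chromatin in recurring combinations.
`cobindlm` treats the binding statuses of many cistromes at one 1-kb genomic
bin as a sentence and trains a BERT-style transformer to reconstruct masked
statuses from their co-binding context. The encoder's contextual embeddings
then serve as per-region representations of the transcriptional regulatory
network (TRN): they support inference of regulator collaborations, in-silico
knockout and omission perturbations, task-specific fine-tuning with optional
prompt vectors, ranking of candidate driver regulators by embedding shift,
and Hi-C contact-map imputation. A synthetic-cistrome generator with planted
co-binding modules and planted driver regulators provides a ground-truth
test surface for every step.

The package is aimed at computational biologists who want a transparent,
fully testable implementation of this modeling family that runs on a single
CPU; no GPU or deep-learning framework is required (the neural-network
engine, a small reverse-mode autodiff over numpy, is part of the package).

## The model

Each genomic bin *b<sub>i</sub>* carries a binding-status vector
*X<sub>i</sub>* ∈ {0,…,4}<sup>P</sup> over *P* cistromes, discretized per
cistrome from binned signal: the binding threshold is the 10th percentile of
signal at peak-carrying bins; binding bins split into signal tertiles
(slightly / moderately / strongly positive), non-binding bins at their
median (strongly / slightly negative). The model computes

- input embeddings `E_i = Emb_position(v) + Emb_token(X_i)`,
- a stack of post-norm transformer blocks (multi-head self-attention +
  feed-forward) giving contextual embeddings `E_i^(TRN)` (P × d),
- a 2-layer perceptron decoder to 5 status logits per position.

Pre-training masks 15% of positions (80% `[MASK]`, 10% random status, 10%
kept) and minimizes a multi-class focal loss (γ = 2) over selected
positions, with a linear warmup–decay schedule and AdamW. Full-scale
defaults mirror the published architecture (P = 6391, d = 768, 8 blocks,
8 heads, max lr 1e-4, batch 32, gradient accumulation 8).

Downstream, a regulator's embedding at a region is the mean of its
cistromes' rows; collaboration is cosine similarity of
regulator embeddings; and the **embedding shift**
`D_m = 1 − cos(Ē_G1,m, Ē_G2,m)` between two outcome-defined region groups
ranks candidate driver regulators.

## Worked example

Generate a synthetic cistrome compendium with four planted co-binding
modules, pre-train a small model, and check that the planted grammar was
recovered (about half a minute on one CPU):

```python
import numpy as np
from cobindlm.encoding import encode_matrix
from cobindlm.synthetic import SyntheticConfig, generate_catalog, generate_signal_matrix
from cobindlm.model import (ModelConfig, MaskingConfig, TrainConfig,
                            pretrain, masked_accuracy)
from cobindlm.representations import (cistrome_embeddings, regulator_embedding,
                                      pairwise_similarity_matrix,
                                      module_similarity_gap)

config = SyntheticConfig(n_regulators=16, cistromes_per_regulator=2,
                         n_modules=4, n_regions=3000, n_drivers=3, seed=0)
catalog, truth = generate_catalog(config)
matrix, peaks = generate_signal_matrix(catalog, truth, config)
tokens = encode_matrix(matrix)
print(f"{tokens.n_regions} regions x {tokens.n_cistromes} cistromes, "
      f"bound fraction {peaks.bound_mask.mean():.2f}")

model_cfg = ModelConfig(seq_len=32, d_model=64, n_blocks=2, n_heads=8, ff_mult=2)
train_cfg = TrainConfig(max_lr=1e-3, batch_size=32, grad_accumulation=1,
                        epochs=8, seed=0, weight_decay=0.0)
model, history = pretrain(tokens.tokens[:2500], model_cfg, MaskingConfig(), train_cfg)
print(f"focal loss {history[0]:.2f} -> {history[-1]:.2f} over {len(history)} steps")

accuracy, majority = masked_accuracy(model, tokens.tokens[2500:],
                                     MaskingConfig(), seed=7)
print(f"masked-token accuracy {accuracy:.3f} vs majority baseline {majority:.3f}")

emb = cistrome_embeddings(model, tokens.tokens[:500])
sims = pairwise_similarity_matrix(regulator_embedding(emb, catalog).mean(axis=0))
gap, p = module_similarity_gap(sims, truth.module_array(catalog.regulators), seed=0)
print(f"within-module minus cross-module similarity: {gap:.3f} "
      f"(permutation p = {p:.4f})")
```

Output:

```
3000 regions x 32 cistromes, bound fraction 0.56
focal loss 5.88 -> 5.04 over 632 steps
masked-token accuracy 0.366 vs majority baseline 0.242
within-module minus cross-module similarity: 0.273 (permutation p = 0.0005)
```

The model predicts masked binding statuses 12 points better than the
majority class — evidence it learned the co-binding grammar, since the
status of a masked cistrome is only predictable from its module partners —
and regulators planted in the same module have clearly more similar
embeddings than regulators from different modules.

A command-line interface covers the pipeline stages
(`cobindlm simulate | encode | pretrain | embed | finetune | interpret |
impute-hic | evaluate`); every run writes a provenance JSON with the config
hash and seed.

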