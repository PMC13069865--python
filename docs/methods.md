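# Methods

This note records the scientific and numerical choices behind `cobindlm`:
the model and its assumptions, the synthetic data it is validated on, the
parameters that matter, and the limits of what the tests demonstrate.

## Binding-status encoding

Cistrome signal tracks are averaged over consecutive 1-kb bins (0-based,
half-open coordinates throughout). Catalog-level quality control keeps
cistromes passing at least four of five metrics (median quality ≥ 25,
uniquely mapped ratio ≥ 60%, PCR bottleneck coefficient ≥ 80%, fraction of
reads in peaks ≥ 1%, ≥ 500 ten-fold confident peaks), plus a peak-count rule
(> 100 peaks for transcription factors, > 1,000 for other regulator classes)
and a genome-coverage rule (> 60% of non-peak regions covered); duplicates
per (regulator, cell label) keep the highest combined QC score, defined here
as the sum of threshold-scaled metric values. Bins overlapping a blacklist
are dropped, and only bins with peak presence in more than two cistromes
(strictly greater; the cutoff is a parameter) are retained, which enriches
for co-binding events.

Per cistrome, the binding threshold is the 10th percentile of signals at
peak-carrying bins, computed with linear interpolation between order
statistics (an exclusive-rank variant can be selected; the choice is
recorded in config). Signal ≥ threshold counts as binding. The binding set
is split into signal tertiles (tokens 2/3/4), the non-binding set at its
median (tokens 0/1). Ties are resolved by stable (signal, bin index)
ordering with `array_split` chunking (larger chunks first), which guarantees
the equal-portion size property (chunk sizes differ by ≤ 1) and makes the
discretization an exact, testable function. A cistrome with no peak bins is
rejected — its threshold is undefined. Whether thresholds should use raw or
normalized signals is not determined by the encoding itself; this
implementation uses raw RPM-like values.

In-silico **knockout** converts every non-"strongly negative" status of a
regulator's cistromes to token 0 (idempotent by construction). **Omission**
removes a regulator's columns while preserving the remaining columns'
original position ids, so position embeddings from a pre-trained model stay
aligned.

## Model and pre-training

Input embedding is the sum of a token table (6 rows: 5 statuses plus
`[MASK]`) and a position table (one row per cistrome). The encoder is a
stack of post-norm transformer blocks — attention, residual, layer norm,
feed-forward, residual, layer norm — in the BERT configuration; pre-norm is
not offered. Attention scaling defaults to the standard per-head
1/√d_head; a `model_dim` mode dividing scores by d_model is available
because the published formula can be read either way, and neither mode is
claimed canonical. The feed-forward width is `ff_mult × d_model` (4 at full
scale; desk-scale experiments use 2, which measured within noise of 4 on
the synthetic grammar at a fraction of the cost). The reconstruction decoder
is Linear(d, d) → ReLU → Linear(d, 5).

Masking selects each position independently with rate 0.15; selected
positions become `[MASK]` (80%), a uniform random real status (10%, never
the mask token), or stay unchanged (10%). All selected positions contribute
to the loss (the BERT convention). The loss is a multi-class focal loss with
γ = 2, summed per region over selected positions and averaged over the
batch; probabilities are clamped at 1e-8 inside the log; γ = 0 reduces it
exactly to masked cross-entropy. Optimization is AdamW at default settings
with a linear warmup (10% of steps) to the maximum learning rate and linear
decay to zero. Training is deterministic given the seed. Full-scale
constants (P = 6391, d = 768, 8 blocks, 8 heads, max lr 1e-4, batch 32,
accumulation 8, 100 epochs) are configuration defaults that are asserted by
tests but never trained here.

Masked-token **accuracy is scored only on positions actually replaced by
`[MASK]`**. The keep/random corruption channels copy the label into the
input, so scoring them rewards an input-copying shortcut and inflates even
a model trained on structure-free data by several points.

## Synthetic cistromes: what is emulated and what is not

The generator plants a block structure: regulators are assigned round-robin
to `n_modules` latent modules (deterministic, so tiny configs stay
balanced); each region activates each module independently with
`module_activity_rate`; cistromes of active-module regulators bind with
`within_module_bind_prob`, others with `background_bind_prob`. Bound
entries draw log-normal signal with median `signal_location` (RPM-like,
default 10) and log-sd `signal_scale` (0.5); unbound entries draw
half-normal noise with scale 5% of `signal_location`, which keeps the
10th-percentile threshold rule meaningful. Labels are driven by a planted
driver subset: the latent score per region is the sum over drivers of their
per-regulator mean binding indicator, plus Gaussian noise; binary tasks
threshold at the median. One RNG stream per artifact (catalog, matrix,
labels, cell-type pair) is derived from the master seed by fixed offsets,
so regenerating labels never perturbs the matrix. Fixed seeds give
bit-identical outputs.

Default rates (`module_activity_rate` 0.6, `within_module_bind_prob` 0.9,
`background_bind_prob` 0.05) were set from an identifiability analysis of
the masked-reconstruction task. For a masked position, the Bayes-optimal
accuracy gain over the majority class is approximately
`a·(0.3·w − (1−w)·q₀)` (a = activity rate, w = within-module binding, q₀ the
lower-half share of the non-binding split): the tertile identity of a bound
token and the half identity of noise tokens are irreducible noise, so the
only learnable signal is module activity. The defaults put this ceiling
near 13 points, comfortably above the 10-point recovery the validation
experiments require; the resulting bound fraction (~0.56) emulates the
co-binding-enriched bins the encoding pipeline retains, not whole-genome
binding density. The generator does **not** emulate read-level noise,
mappability, fragment-length effects, peak-caller artifacts, real genome
coordinates, or inter-module correlation; passing tests therefore show that
the implementation recovers planted structure under clean conditions, not
that it matches real-compendium performance.

For driver-identification experiments, `spread_drivers=True` samples at most
one driver per module. With two drivers in one module, every member of that
module out-shifts the lone drivers of other modules — the causal signal is
absorbed by module co-binding and no ranking method could attribute it; one
driver per module keeps the planted signal attributable.

## Representations and interpretation

Regulator embeddings are arithmetic means of cistrome embeddings (taken
from the final encoder block; no layer choice is exposed as signal).
Regulators whose cistromes were all omitted are excluded from matrices
rather than zero-filled. Group averages deduplicate region ids. Embedding
shift is 1 − cosine of group-mean embeddings, invariant to positive
rescaling. Ranks are descending in shift with average ranks on ties and
lexicographic regulator order for determinism; the normalized ranking score
1 − (rank−1)/(M−1) is this package's construction (only the averaging of
scores across modalities is inherited from the method family). Outcome
groups follow fixed thresholds: expression Δlog1p > 1 vs −0.5…0.5;
accessibility log2FC > 2 vs the 40,000 covered regions of smallest |log2FC|
(scaled as min(40,000, 50% of covered regions) on small genomes, with
provenance recorded). Composite scores average two modalities; the top 25
are reported as key regulators; cofactors of a focal regulator are the top
30 by embedding similarity over a region set, optionally annotated with the
embedding shift induced by knocking out the focal regulator.

The fine-tuning universal decoder is a width-1 convolution over the
regulator axis (channel mixing d → d), ReLU, then a perceptron to one
output node. The perceptron input **flattens the regulator axis** (one
read-out weight vector per regulator) rather than mean-pooling: pooling
spreads the task gradient uniformly over all regulator positions, which
erases the driver-selective embedding changes that shift-based
interpretation depends on (measured directly: mean driver rank degraded
from 6 to 38 with a pooled head, and stayed at the ceiling with the
flattened head). A pooled variant remains available for heads that must
accept a variable regulator count. Gene-level tasks max-pool embeddings
over the 9 bins around the TSS; windows truncated by a chromosome edge are
a hard error unless replicate-edge padding is enabled. Prompts narrower or
wider than the model dimension pass through a learned linear projection
before concatenation; accessibility-style prompts are per-region, cell-level
prompts are shared across regions. Checkpoint selection during fine-tuning
keeps the epoch with the lowest validation loss.

## Contact-map imputation

The three input channels of a window of N 1-kb bins are: the O/E
low-resolution map bilinearly up-sampled 5× (corner-aligned interpolation,
so coarse grid values are preserved); cosine similarity of region-mean
embeddings, with entries touching bins absent from pre-training replaced by
the mean similarity at the same distance over valid pairs (global mean as
fallback); and (1 + D_g)^−0.75 with D_g in bin units — bins keep the
channel dimensionless and within (0, 1]. The CNN is 3 → C → C → 1 with
square kernels and same padding (full scale: C = 64, 13 × 13), ReLU after
the first two layers and a linear output; training minimizes MSE with AdamW
under a warmup–decay schedule. Windows slide diagonally (1,000 bins, step
200 at full scale) with a final window clipped to the chromosome end;
chromosome-to-split assignment follows the standard train/val/test lists
and is remappable for synthetic genomes. Desk-scale experiments use 24–32
bin windows and C = 8–16 with 3–5-bin kernels; with standard initialization
the identity-representable toy needs roughly a thousand optimizer steps
(seconds of CPU) to drive MSE below 1e-3.

## Benchmark plumbing

The cell-type-specificity baseline multiplies a regulator's candidate-peak
mask (union of peak bins when at least five other cistromes exist, else a
motif-bin mask) elementwise with accessibility signal. Cell-type-specific
sites require ChIP signal > 3 ("exceed" read as strict), at least 3-fold
over the other cell type (read as ≥, both readings configurable),
|log2 accessibility fold change| < 0.5, and accessibility > 3 in both cell
types; pairs with fewer than 50 specific events or ≥ 5-fold present/absent
imbalance are rejected. Zero denominators use a pseudo-count of 0.1 and are
logged. Genome-background normalization divides by the genome-wide mean
read density (the formula is an interpretation; no canonical one exists).
AUROC is the rank-based (Mann–Whitney) area; AUPRC is trapezoidal along the
threshold-ordered precision-recall curve, so score ties form zero-width
segments.

## Problem sizes and numerical notes

The validation experiments use: grammar recovery — 32 regulators × 2
cistromes, 4 modules, 5,000 regions (4,000 train), d = 64, 2 blocks, 5
epochs at max lr 1e-3 without weight decay, plus a column-shuffled control;
driver identification — three replicate worlds of 64 regulators × 1
cistrome, 8 modules, 4 spread drivers, 3,000 regions, label noise sd 1.0,
fine-tuned 8 epochs at max lr 3e-3 with the last block trainable;
imputation — 3–6 windows of 24 bins. Parameters are float32 (scalar
operands are coerced to the tensor dtype so graphs never silently upcast);
gradient checks run in float64. The permutation test for the module
similarity gap uses 2,000 label permutations with the +1 correction.

## Known limitations

- No dropout, no pre-norm option, no fused or memory-efficient attention;
  full-scale pre-training is a configuration target, not a supported run.
- The synthetic generator's independence assumptions (modules independent
  across regions, binding independent given activity) make planted tasks
  cleaner than real data; absolute metric values do not transfer.
- Per-task hyperparameters of the original fine-tuning applications
  (losses, epochs, frozen-layer counts per real dataset) are not
  reproduced; defaults are explicit configuration, not claims.
- The Hi-C module handles dense matrices; cooler-backed storage is an
  adapter contract, not implemented I/O.
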