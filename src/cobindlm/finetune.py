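"""Task-specific fine-tuning with selective freezing and prompt vectors.

Fine-tuning keeps the pre-trained knowledge by freezing the embedding tables
and the early encoder blocks; only the last blocks and a task head train.
Region tasks use a universal head (width-1 convolution over the regulator
axis, then a perceptron to one output node); gene tasks first max-pool
embeddings over the 9 bins around the TSS.  Prompt-enhanced variants
concatenate an external context vector (projected to model width when
necessary) with a regulator embedding before the decoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .encoding import CistromeCatalog
from .model import CoBindingModel, TrainConfig, lr_schedule
from .nn import Tensor

logger = logging.getLogger(__name__)

GENE_WINDOW = 9  # TSS bin +/- 4


@dataclass
class TaskSpec:
    objective: str = "classification"    # or "regression"
    granularity: str = "region"          # or "gene"
    loss: str = "bce"                    # "bce" | "focal" | "mse"
    label_source: str = ""

    def __post_init__(self):
        if self.objective not in ("classification", "regression"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.granularity not in ("region", "gene"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if self.loss not in ("bce", "focal", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class PromptVector:
    """External context vector: accessibility / transcriptome / sequence."""

    values: np.ndarray
    kind: str = "accessibility-embedding"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("prompt values must be finite")

    @property
    def width(self) -> int:
        return self.values.shape[-1]


@dataclass
class FreezePolicy:
    n_trainable_final_blocks: int = 1


def freeze(model: CoBindingModel, policy: FreezePolicy) -> CoBindingModel:
    """Freeze embeddings and early blocks; last n blocks stay trainable.

    The pre-training reconstruction decoder is frozen too; task heads are
    separate modules and always trainable.
    """
    n = policy.n_trainable_final_blocks
    if not 0 <= n <= len(model.blocks):
        raise ValueError(f"n_trainable_final_blocks must lie in [0, {len(model.blocks)}]")
    model.set_trainable(False)
    for block in model.blocks[len(model.blocks) - n:]:
        block.set_trainable(True)
    return model


class RegionHead(nn.Module):
    """Universal task head: width-1 convolution over the regulator axis
    (channel mixing d -> d), ReLU, then a perceptron to a single output node.

    With ``n_regulators`` given, the regulator axis is flattened into the
    perceptron so every regulator keeps its own read-out weights (gradients
    stay regulator-selective); without it, regulators are mean-pooled and the
    head accepts any M.
    """

    def __init__(self, d_model: int, n_regulators: int | None = None,
                 hidden: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        hidden = hidden or d_model
        self.n_regulators = n_regulators
        self.conv = nn.Linear(d_model, d_model, rng)   # width-1 kernel over regulators
        in_width = d_model * n_regulators if n_regulators else d_model
        self.fc1 = nn.Linear(in_width, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def __call__(self, reg_emb: Tensor) -> Tensor:
        """(..., M, d) -> (...,) raw scalar (sigmoid applied downstream)."""
        x = self.conv(reg_emb).relu()
        if self.n_regulators:
            if x.shape[-2] != self.n_regulators:
                raise ValueError("regulator count does not match the head")
            x = x.reshape(*x.shape[:-2], x.shape[-2] * x.shape[-1])
        else:
            x = x.mean(axis=-2)
        out = self.fc2(self.fc1(x).relu())
        return out.reshape(out.shape[:-1])


class PromptHead(nn.Module):
    """Imputation head: concat(regulator embedding, projected prompt) -> MLP."""

    def __init__(self, d_model: int, prompt_width: int, hidden: int | None = None,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        hidden = hidden or d_model
        self.projection = (nn.Linear(prompt_width, d_model, rng)
                           if prompt_width != d_model else None)
        self.fc1 = nn.Linear(2 * d_model, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def __call__(self, reg_emb: Tensor, prompt: Tensor) -> Tensor:
        joined = concat_prompt(reg_emb, prompt, self.projection)
        out = self.fc2(self.fc1(joined).relu())
        return out.reshape(out.shape[:-1])


def concat_prompt(reg_emb: Tensor, prompt, projection=None) -> Tensor:
    """Concatenate a prompt vector onto a regulator embedding (output 2d).

    Prompts whose width differs from the model width must come with a learned
    linear ``projection``; model-width prompts concatenate directly.
    """
    if isinstance(prompt, PromptVector):
        prompt = prompt.values
    p = prompt if isinstance(prompt, Tensor) else Tensor(np.asarray(prompt, dtype=float))
    d = reg_emb.shape[-1]
    if p.shape[-1] != d:
        if projection is None:
            raise ValueError(
                f"prompt width {p.shape[-1]} != model width {d} and no projection given")
        p = projection(p)
    if p.ndim < reg_emb.ndim:  # broadcast one prompt over leading axes
        target = reg_emb.shape[:-1] + (d,)
        p = Tensor(np.broadcast_to(p.data, target)) if not p.requires_grad else \
            p.reshape(*([1] * (reg_emb.ndim - p.ndim)), *p.shape) * Tensor(np.ones(target))
    return nn.concat([reg_emb, p], axis=-1)


def gene_pool(window_embeddings) -> Tensor | np.ndarray:
    """Elementwise max over the 9 bins around a TSS: (..., 9, M, d) -> (..., M, d)."""
    if window_embeddings.shape[-3] != GENE_WINDOW:
        raise ValueError(f"gene windows must contain exactly {GENE_WINDOW} bins")
    if isinstance(window_embeddings, Tensor):
        return window_embeddings.max(axis=-3)
    return np.asarray(window_embeddings).max(axis=-3)


def make_gene_windows(n_regions: int, tss_bins: np.ndarray,
                      pad_edges: bool = False) -> np.ndarray:
    """(G, 9) region indices for each TSS bin; edges error unless padded."""
    tss = np.asarray(tss_bins)
    offsets = np.arange(-4, 5)
    windows = tss[:, None] + offsets
    if windows.min() < 0 or windows.max() >= n_regions:
        if not pad_edges:
            raise ValueError("gene window truncated by chromosome edge "
                             "(enable pad_edges for replicate-edge padding)")
        windows = np.clip(windows, 0, n_regions - 1)
    return windows


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _binary_loss(raw: Tensor, labels: np.ndarray, kind: str, gamma: float) -> Tensor:
    y = np.asarray(labels, dtype=float)
    p = raw.sigmoid()
    p_true = p * Tensor(y) + (1.0 - p) * Tensor(1.0 - y)
    if kind == "focal":
        per = (1.0 - p_true) ** float(gamma) * (-(p_true.log(eps=1e-8)))
    else:
        per = -(p_true.log(eps=1e-8))
    return per.mean()


def _mse_loss(raw: Tensor, labels: np.ndarray) -> Tensor:
    return ((raw - Tensor(np.asarray(labels, dtype=float))) ** 2.0).mean()


# ---------------------------------------------------------------------------
# the fine-tuning loop
# ---------------------------------------------------------------------------

def _split_indices(n: int, rng: np.random.Generator,
                   fractions=(0.7, 0.15, 0.15)) -> dict[str, np.ndarray]:
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {"train": order[:n_train],
            "val": order[n_train:n_train + n_val],
            "test": order[n_train + n_val:]}


def finetune_task(
    model: CoBindingModel,
    dataset: dict,
    task: TaskSpec,
    policy: FreezePolicy,
    train: TrainConfig,
    head: nn.Module | None = None,
    target_regulator: str | None = None,
) -> tuple[CoBindingModel, nn.Module, dict]:
    """Fine-tune on a labeled dataset; returns (model, head, metrics).

    ``dataset`` keys: ``tokens`` (N, P), ``labels``, ``catalog``; optional
    ``position_ids``, ``prompt`` (:class:`PromptVector`), ``splits``
    (train/val/test index arrays), ``tss_bins`` for gene granularity.
    The checkpoint with the lowest validation loss is restored before
    computing held-out metrics.
    """
    tokens = np.asarray(dataset["tokens"])
    labels = np.asarray(dataset["labels"])
    catalog: CistromeCatalog = dataset["catalog"]
    position_ids = dataset.get("position_ids")
    prompt: PromptVector | None = dataset.get("prompt")
    rng = np.random.default_rng(train.seed)

    if task.granularity == "gene":
        windows = make_gene_windows(tokens.shape[0], dataset["tss_bins"],
                                    dataset.get("pad_edges", False))
        n_items = windows.shape[0]
    else:
        windows = None
        n_items = tokens.shape[0]
    if labels.shape[0] != n_items:
        raise ValueError("labels are not aligned with regions/genes")

    splits = dataset.get("splits") or _split_indices(n_items, rng)
    if task.objective == "classification":
        if np.unique(labels[splits["train"]]).size < 2:
            raise ValueError("degenerate single-class training labels")
    flags = []
    if task.objective == "regression" and np.var(labels[splits["train"]]) == 0:
        flags.append("constant_labels")
        logger.warning("regression on constant labels: R^2 undefined")

    freeze(model, policy)
    d = model.config.d_model
    if head is None:
        if target_regulator is not None:
            if prompt is None:
                raise ValueError("imputation mode requires a prompt for the cell type")
            head = PromptHead(d, prompt.width, seed=train.seed)
        else:
            head = RegionHead(d, n_regulators=len(catalog.regulators),
                              seed=train.seed)
    G = Tensor(catalog.grouping_matrix())      # (M, P), constant
    regs = catalog.regulators
    target_idx = regs.index(target_regulator) if target_regulator is not None else None

    params = model.trainable_parameters() + head.trainable_parameters()
    opt = nn.AdamW(params, lr=train.max_lr, weight_decay=train.weight_decay)

    def predict_raw(idx: np.ndarray) -> Tensor:
        if windows is None:
            enc = model.encode(model.embed_input(tokens[idx], position_ids))
            reg_emb = G @ enc                       # (B, M, d)
        else:
            w = windows[idx]                         # (B, 9)
            enc = model.encode(model.embed_input(tokens[w.reshape(-1)], position_ids))
            enc = enc.reshape(w.shape[0], GENE_WINDOW, tokens.shape[1], d)
            reg_emb = gene_pool(G @ enc)
        if target_idx is not None:
            target_emb = reg_emb[:, target_idx, :]
            # accessibility-style prompts are per-region; cell-level prompts
            # are a single vector shared across regions
            pv = prompt.values[idx] if prompt.values.ndim == 2 else prompt.values
            return head(target_emb, Tensor(pv.astype(np.float64)))
        return head(reg_emb)

    def batch_loss(idx: np.ndarray) -> Tensor:
        raw = predict_raw(idx)
        if task.objective == "classification":
            return _binary_loss(raw, labels[idx], task.loss, train.gamma)
        return _mse_loss(raw, labels[idx])

    n_train = splits["train"].size
    batches = int(np.ceil(n_train / train.batch_size))
    total_steps = max(1, train.epochs * batches)
    best = (np.inf, None)
    val_history = []
    step = 0
    for _ in range(train.epochs):
        order = rng.permutation(splits["train"])
        for bi in range(batches):
            idx = order[bi * train.batch_size:(bi + 1) * train.batch_size]
            loss = batch_loss(idx)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite fine-tuning loss")
            loss.backward()
            step += 1
            opt.step(lr=lr_schedule(min(step, total_steps), total_steps, train))
            opt.zero_grad()
        with nn.no_grad():
            val_loss = float(batch_loss(splits["val"]).data) \
                if splits["val"].size else float(loss.data)
        val_history.append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, [p.data.copy() for p in params])
    if best[1] is not None:
        for p, a in zip(params, best[1]):
            p.data = a

    metrics: dict = {"val_loss": best[0], "val_history": val_history,
                     "flags": flags}
    test = splits["test"]
    if test.size:
        with nn.no_grad():
            raw = predict_raw(test).data
        if task.objective == "classification":
            from .evaluation import metrics as rank_metrics
            scores = 1.0 / (1.0 + np.exp(-raw))
            if np.unique(labels[test]).size == 2:
                metrics.update(rank_metrics(scores, labels[test]))
        else:
            resid = raw - labels[test]
            metrics["mse"] = float(np.mean(resid**2))
            var = np.var(labels[test])
            metrics["r2"] = float(1 - np.mean(resid**2) / var) if var > 0 else float("nan")
    return model, head, metrics
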