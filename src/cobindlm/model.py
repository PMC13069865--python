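"""The masked language model over regulator co-binding tokens.

Each 1-kb genomic region is one training example: a sequence of binding-status
tokens, one per cistrome, at fixed positions.  The model sums a token
embedding and a position embedding per cistrome, passes the sequence through a
stack of post-norm transformer blocks, and reconstructs masked statuses with a
two-layer perceptron decoder producing 5 logits per position.  Training
follows the BERT recipe (15% selection, 80/10/10 mask/random/keep) with a
multi-class focal loss restricted to selected positions, a linear
warmup-decay learning-rate schedule, and AdamW.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .encoding import MASK_TOKEN_ID, VOCAB_SIZE
from .nn import Tensor

N_STATUSES = 5


@dataclass
class ModelConfig:
    seq_len: int                     # P: number of cistrome positions
    d_model: int = 768
    n_blocks: int = 8
    n_heads: int = 8
    vocab_size: int = VOCAB_SIZE     # 5 statuses + [MASK]
    decoder_hidden: int | None = None  # defaults to d_model
    ff_mult: int = 4
    attention_scaling: str = "per_head"  # or "model_dim" (scores / d_model)

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.vocab_size != VOCAB_SIZE:
            raise ValueError(f"vocab_size must be {VOCAB_SIZE} (5 statuses + mask)")
        if self.decoder_hidden is None:
            self.decoder_hidden = self.d_model

    @classmethod
    def full_scale(cls) -> "ModelConfig":
        """The full-compendium architecture: P=6391, d=768, 8 blocks, 8 heads."""
        return cls(seq_len=6391, d_model=768, n_blocks=8, n_heads=8)


@dataclass
class MaskingConfig:
    select_rate: float = 0.15
    mask_rate: float = 0.8
    random_rate: float = 0.1
    keep_rate: float = 0.1
    mask_token_id: int = MASK_TOKEN_ID

    def __post_init__(self):
        if not 0.0 <= self.select_rate <= 1.0:
            raise ValueError("select_rate must lie in [0, 1]")
        if abs(self.mask_rate + self.random_rate + self.keep_rate - 1.0) > 1e-9:
            raise ValueError("mask_rate + random_rate + keep_rate must equal 1")


@dataclass
class TrainConfig:
    max_lr: float = 1e-4
    warmup_fraction: float = 0.1
    batch_size: int = 32
    grad_accumulation: int = 8
    epochs: int = 100
    gamma: float = 2.0               # focal focusing parameter
    seed: int = 0
    weight_decay: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


class CoBindingModel(nn.Module):
    """Embedding tables + transformer encoder + reconstruction decoder."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.token_table = nn.Embedding(config.vocab_size, config.d_model, rng)
        self.position_table = nn.Embedding(config.seq_len, config.d_model, rng)
        self.blocks = [
            nn.TransformerBlock(config.d_model, config.n_heads, config.ff_mult,
                                rng, config.attention_scaling)
            for _ in range(config.n_blocks)
        ]
        self.dec1 = nn.Linear(config.d_model, config.decoder_hidden, rng)
        self.dec2 = nn.Linear(config.decoder_hidden, N_STATUSES, rng)

    # -- forward pieces ----------------------------------------------------
    def embed_input(self, tokens: np.ndarray,
                    position_ids: np.ndarray | None = None) -> Tensor:
        """Input embedding: position row + token row per cistrome position."""
        tokens = np.asarray(tokens)
        if tokens.min(initial=0) < 0 or tokens.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id outside vocabulary")
        if position_ids is None:
            position_ids = np.arange(tokens.shape[-1])
        return self.token_table(tokens) + self.position_table(np.asarray(position_ids))

    def encode(self, emb: Tensor) -> Tensor:
        """Apply the transformer blocks; the contextual co-binding embedding."""
        if emb.shape[-1] != self.config.d_model:
            raise ValueError("embedding width does not match d_model")
        x = emb
        for block in self.blocks:
            x = block(x)
        return x

    def decode_logits(self, encoded: Tensor) -> Tensor:
        """Per-position 2-layer perceptron to 5 status logits."""
        return self.dec2(self.dec1(encoded).relu())

    def forward(self, tokens: np.ndarray,
                position_ids: np.ndarray | None = None) -> Tensor:
        return self.decode_logits(self.encode(self.embed_input(tokens, position_ids)))

    # -- checkpointing -----------------------------------------------------
    def save(self, path):
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "CoBindingModel":
        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig(**json.loads(str(z["__config__"])))
            model = cls(config)
            model.load_arrays([z[f"p{i}"] for i in range(len(model.parameters()))])
        return model

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


# ---------------------------------------------------------------------------
# masking, loss, schedule
# ---------------------------------------------------------------------------

def apply_masking(
    tokens: np.ndarray, masking: MaskingConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BERT-style corruption of a token array (any shape, values in {0..4}).

    Returns (corrupted tokens, selected boolean mask, labels).  Labels are the
    original tokens, defined only where selected.  Selected positions are
    replaced by the mask token, a uniform-random real status, or left
    unchanged, with the configured conditional rates; unchanged positions
    still count as prediction targets.
    """
    tokens = np.asarray(tokens)
    if tokens.min(initial=0) < 0 or tokens.max(initial=0) >= N_STATUSES:
        raise ValueError("input tokens must be real statuses in {0..4}")
    u = rng.random(tokens.shape)
    selected = u < masking.select_rate
    action = rng.random(tokens.shape)
    corrupted = tokens.copy()
    mask_here = selected & (action < masking.mask_rate)
    random_here = selected & (action >= masking.mask_rate) & \
        (action < masking.mask_rate + masking.random_rate)
    corrupted[mask_here] = masking.mask_token_id
    corrupted[random_here] = rng.integers(0, N_STATUSES, size=int(random_here.sum()))
    labels = tokens.copy()
    return corrupted, selected, labels


def focal_loss(
    probabilities: Tensor, labels: np.ndarray, selected: np.ndarray,
    gamma: float = 2.0, eps: float = 1e-8,
) -> Tensor:
    """Multi-class focal loss over selected positions.

    probabilities: (..., P, 5) rows summing to 1; labels/selected: (..., P).
    Per region the loss is the sum over selected positions of
    -(1 - p_true)^gamma * log(p_true); batched inputs are averaged over the
    leading axes.  At gamma=0 this is the masked cross-entropy.
    """
    labels = np.asarray(labels)
    selected = np.asarray(selected, dtype=bool)
    dtype = probabilities.data.dtype
    onehot = np.zeros(probabilities.shape, dtype=dtype)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    onehot *= selected[..., None]
    p_sel = (probabilities * Tensor(onehot)).sum(axis=-1)  # p_true where selected
    # keep unselected positions out of the log/pow path entirely
    p_safe = p_sel + Tensor((~selected).astype(dtype))
    per_pos = (1.0 - p_safe) ** float(gamma) * (-(p_safe.log(eps=eps)))
    per_region = per_pos.sum(axis=-1)
    if per_region.ndim == 0:
        return per_region
    return per_region.mean()


def lr_schedule(step: int, total_steps: int, train: TrainConfig) -> float:
    """Linear warmup from 0 to max_lr, then linear decay back to 0."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    warmup = train.warmup_fraction * total_steps
    if step <= warmup:
        return train.max_lr * (step / warmup if warmup else 1.0)
    return train.max_lr * (total_steps - step) / (total_steps - warmup)


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------

def pretrain(
    token_matrix: np.ndarray,
    model_config: ModelConfig | None = None,
    masking: MaskingConfig | None = None,
    train: TrainConfig | None = None,
    position_ids: np.ndarray | None = None,
    model: CoBindingModel | None = None,
) -> tuple[CoBindingModel, list[float]]:
    """Masked-reconstruction pre-training on a regions x cistromes token array.

    Deterministic given ``train.seed``.  The loss history holds one value per
    optimizer step (losses averaged over the accumulated micro-batches).
    """
    tokens = np.asarray(token_matrix)
    if tokens.size == 0:
        raise ValueError("token matrix is empty")
    masking = masking or MaskingConfig()
    train = train or TrainConfig()
    if model is None:
        if model_config is None:
            model_config = ModelConfig(seq_len=tokens.shape[1], d_model=64,
                                       n_blocks=2, n_heads=8, ff_mult=2)
        model = CoBindingModel(model_config, seed=train.seed)

    rng = np.random.default_rng(train.seed)
    n = tokens.shape[0]
    batches_per_epoch = int(np.ceil(n / train.batch_size))
    steps_per_epoch = int(np.ceil(batches_per_epoch / train.grad_accumulation))
    total_steps = train.epochs * steps_per_epoch
    opt = nn.AdamW(model.parameters(), lr=train.max_lr,
                   weight_decay=train.weight_decay)

    history: list[float] = []
    step = 0
    for _ in range(train.epochs):
        order = rng.permutation(n)
        accum_losses: list[float] = []
        for bi in range(batches_per_epoch):
            batch = tokens[order[bi * train.batch_size:(bi + 1) * train.batch_size]]
            corrupted, sel, labels = apply_masking(batch, masking, rng)
            logits = model.forward(corrupted, position_ids)
            loss = focal_loss(logits.softmax(axis=-1), labels, sel, train.gamma)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at step {step}: {float(loss.data)}")
            (loss * (1.0 / train.grad_accumulation)).backward()
            accum_losses.append(float(loss.data))
            if (bi + 1) % train.grad_accumulation == 0 or bi == batches_per_epoch - 1:
                step += 1
                opt.step(lr=lr_schedule(min(step, total_steps), total_steps, train))
                opt.zero_grad()
                history.append(float(np.mean(accum_losses)))
                accum_losses = []
    return model, history


def masked_accuracy(
    model: CoBindingModel, tokens: np.ndarray, masking: MaskingConfig,
    seed: int = 0, batch_size: int = 64,
) -> tuple[float, float]:
    """(model accuracy, majority-class baseline) on freshly masked tokens.

    Scored only on positions actually replaced by the mask token, where the
    input carries no direct evidence of the label.
    """
    rng = np.random.default_rng(seed)
    corrupted, sel, labels = apply_masking(np.asarray(tokens), masking, rng)
    sel = sel & (corrupted == masking.mask_token_id)
    preds = np.empty_like(labels)
    with nn.no_grad():
        for lo in range(0, tokens.shape[0], batch_size):
            logits = model.forward(corrupted[lo:lo + batch_size])
            preds[lo:lo + batch_size] = logits.data.argmax(axis=-1)
    true = labels[sel]
    counts = np.bincount(true, minlength=N_STATUSES)
    majority = counts.max() / counts.sum()
    accuracy = float((preds[sel] == true).mean())
    return accuracy, float(majority)
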