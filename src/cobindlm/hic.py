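"""Contact-map imputation from low-resolution maps plus embedding similarity.

A window of N 1-kb bins yields a 3-channel N x N input: (1) the O/E
low-resolution contact map bilinearly up-sampled from 5-kb resolution,
(2) the pairwise cosine-similarity map of region-mean co-binding embeddings,
and (3) a genomic-distance channel (1 + D_g)^-0.75 with D_g in bin units.
A three-layer CNN (3 -> C -> C -> 1 channels, square kernels, same padding)
maps the stack to the predicted high-resolution map and trains against
O/E-normalized targets with mean-squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import nn
from .nn import Tensor

DISTANCE_EXPONENT = -0.75

#: chromosome-to-split assignment used with real genomes (remappable)
CHROMOSOME_SPLITS = {
    "train": ("1", "4", "7", "10", "13", "17", "18"),
    "val": ("3", "6", "9", "12", "16", "19", "20", "X"),
    "test": ("2", "5", "8", "11", "14", "15", "21", "22"),
}


@dataclass
class ContactWindow:
    """One training example: 3-channel input and its high-resolution target."""

    low_res_oe: np.ndarray     # (N, N)
    similarity: np.ndarray     # (N, N) in [-1, 1]
    distance: np.ndarray       # (N, N) in (0, 1]
    target: np.ndarray | None  # (N, N)
    origin: int = 0

    def stacked(self) -> np.ndarray:
        if not (self.low_res_oe.shape == self.similarity.shape == self.distance.shape):
            raise ValueError("channels must share one shape")
        return np.stack([self.low_res_oe, self.similarity, self.distance])


def upsample_bilinear(map_low: np.ndarray, factor: int = 5) -> np.ndarray:
    """Bilinear up-sampling of a square contact map by an integer factor.

    Grid corners are aligned, so values at the coarse grid points are
    preserved and intermediate positions are linear combinations of the four
    nearest coarse bins.
    """
    m = np.asarray(map_low, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact map must be square")
    n = m.shape[0]
    out_n = n * factor
    if n == 1:
        return np.full((factor, factor), m[0, 0])
    grid = np.arange(n, dtype=float)
    interp = RegularGridInterpolator((grid, grid), m, method="linear")
    coords = np.linspace(0.0, n - 1.0, out_n)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return interp(np.stack([xx, yy], axis=-1))


def distance_channel(n: int, exponent: float = DISTANCE_EXPONENT) -> np.ndarray:
    """(1 + |a - b|)^exponent with genomic distance in bin units."""
    if n < 1:
        raise ValueError("window must contain at least one bin")
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return (1.0 + d) ** exponent


def similarity_channel(
    embeddings: np.ndarray,
    excluded: np.ndarray | None = None,
    distance_profile: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise cosine similarity of region-mean embeddings over a window.

    Entries touching ``excluded`` bins (bins absent from pre-training input)
    are replaced by the mean similarity at the same genomic distance computed
    over non-excluded pairs (or by ``distance_profile`` if supplied); if no
    valid pair exists at a distance, the global mean is used.
    """
    E = np.asarray(embeddings, dtype=float)
    norms = np.linalg.norm(E, axis=1)
    if (norms == 0).any():
        raise ValueError("zero embedding vector in window")
    U = E / norms[:, None]
    S = U @ U.T
    n = S.shape[0]
    if excluded is None or len(excluded) == 0:
        return S
    excluded = np.asarray(excluded)
    bad = np.zeros(n, dtype=bool)
    bad[excluded] = True
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    touches = bad[:, None] | bad[None, :]
    good_pairs = ~touches
    global_mean = S[good_pairs].mean() if good_pairs.any() else 0.0
    out = S.copy()
    for d in np.unique(dist[touches]):
        at_d = dist == d
        if distance_profile is not None and d < len(distance_profile):
            fill = distance_profile[d]
        else:
            valid = at_d & good_pairs
            fill = S[valid].mean() if valid.any() else global_mean
        out[at_d & touches] = fill
    return out


def observed_over_expected(matrix: np.ndarray) -> np.ndarray:
    """O/E normalization: divide each diagonal by its mean contact frequency."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    out = np.zeros_like(m)
    for d in range(n):
        idx = np.arange(n - d)
        vals = m[idx, idx + d]
        expected = vals.mean()
        if expected > 0:
            out[idx, idx + d] = vals / expected
            out[idx + d, idx] = out[idx, idx + d]
    return out


class HiCImputerCNN(nn.Module):
    """3 -> channels -> channels -> 1 convolutional imputer, same padding.

    Full-scale configuration: 64 feature channels and 13 x 13 kernels; ReLU
    after the first two layers, linear output.
    """

    def __init__(self, channels: int = 64, kernel: int = 13, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2d(3, channels, kernel, rng)
        self.conv2 = nn.Conv2d(channels, channels, kernel, rng)
        self.conv3 = nn.Conv2d(channels, 1, kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(B, 3, N, N) -> (B, 1, N, N)."""
        if x.shape[-3] != 3:
            raise ValueError("input must have 3 channels")
        return self.conv3(self.conv2(self.conv1(x).relu()).relu())

    def predict(self, window: ContactWindow) -> np.ndarray:
        with nn.no_grad():
            out = self(Tensor(window.stacked()[None].astype(nn.DTYPE)))
        return out.data[0, 0]


def window_sampler(
    chromosome_length: int, window: int = 1000, step: int = 200,
    chromosome: str | None = None,
    splits: dict[str, tuple] = CHROMOSOME_SPLITS,
) -> tuple[list[int], str | None]:
    """Diagonal sliding-window origins (bins) and the chromosome's split.

    Origins are multiples of ``step``; a final window clipped to the
    chromosome end is appended when the last stride overshoots.
    """
    if chromosome_length < window:
        import warnings
        warnings.warn("chromosome shorter than the window: no origins")
        return [], _split_of(chromosome, splits)
    origins = list(range(0, chromosome_length - window + 1, step))
    if origins[-1] != chromosome_length - window:
        origins.append(chromosome_length - window)
    return origins, _split_of(chromosome, splits)


def _split_of(chromosome, splits):
    if chromosome is None:
        return None
    name = str(chromosome).removeprefix("chr")
    for split, chroms in splits.items():
        if name in chroms:
            return split
    return None


def train_imputer(
    windows: np.ndarray,
    targets: np.ndarray,
    steps: int = 200,
    lr: float = 3e-3,
    batch_size: int = 2,
    channels: int = 64,
    kernel: int = 13,
    seed: int = 0,
    val_windows: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
) -> tuple[HiCImputerCNN, dict]:
    """Train the CNN with mean-squared error; deterministic given the seed.

    ``windows``: (n, 3, N, N); ``targets``: (n, N, N).  Returns the model and
    per-split loss histories.
    """
    windows = np.asarray(windows, dtype=nn.DTYPE)
    targets = np.asarray(targets, dtype=nn.DTYPE)
    if windows.shape[0] == 0:
        raise ValueError("empty training split")
    model = HiCImputerCNN(channels=channels, kernel=kernel, seed=seed)
    if steps == 0:
        return model, {"train": [], "val": []}
    rng = np.random.default_rng(seed)
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=0.0)
    history = {"train": [], "val": []}
    n = windows.shape[0]
    warmup = max(1, steps // 10)
    for step in range(steps):
        # linear warmup then linear decay, mirroring the pre-training schedule
        step_lr = lr * (step + 1) / warmup if step < warmup \
            else lr * (steps - step) / max(1, steps - warmup)
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        pred = model(Tensor(windows[idx]))
        loss = ((pred.reshape(pred.shape[0], *pred.shape[2:])
                 - Tensor(targets[idx])) ** 2.0).mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite imputation loss")
        loss.backward()
        opt.step(lr=step_lr)
        opt.zero_grad()
        history["train"].append(float(loss.data))
    if val_windows is not None:
        with nn.no_grad():
            pred = model(Tensor(np.asarray(val_windows, dtype=nn.DTYPE)))
            val_loss = float(np.mean(
                (pred.data[:, 0] - np.asarray(val_targets, dtype=nn.DTYPE)) ** 2))
        history["val"].append(val_loss)
    return model, history
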