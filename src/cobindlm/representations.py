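"""Extracting and comparing contextual regulator embeddings.

The encoder output assigns each region a P x d matrix of cistrome-level
contextual embeddings.  A regulator's embedding at a region is the arithmetic
mean of its cistromes' rows; similarity between regulators is cosine
similarity of these vectors, and the "embedding shift" of a regulator between
two region groups is one minus the cosine of its group-mean embeddings.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .encoding import CistromeCatalog
from .model import CoBindingModel


def cistrome_embeddings(
    model: CoBindingModel, tokens: np.ndarray,
    position_ids: np.ndarray | None = None, batch_size: int = 64,
) -> np.ndarray:
    """Encoder output for every region: (N, P, d) from the final block."""
    tokens = np.asarray(tokens)
    out = np.empty((*tokens.shape, model.config.d_model), dtype=np.float64)
    with nn.no_grad():
        for lo in range(0, tokens.shape[0], batch_size):
            emb = model.embed_input(tokens[lo:lo + batch_size], position_ids)
            out[lo:lo + batch_size] = model.encode(emb).data
    return out


def regulator_embedding(
    cistrome_emb: np.ndarray, catalog: CistromeCatalog,
    regulators: list[str] | None = None,
) -> np.ndarray:
    """Mean of each regulator's cistrome rows: (..., P, d) -> (..., M, d)."""
    G = catalog.grouping_matrix(regulators)
    return np.einsum("mp,...pd->...md", G, np.asarray(cistrome_emb))


def mean_region_embedding(regulator_level: np.ndarray) -> np.ndarray:
    """Average over regulators: the region-level summary vector."""
    regulator_level = np.asarray(regulator_level)
    if regulator_level.size == 0:
        raise ValueError("empty embedding matrix")
    return regulator_level.mean(axis=-2)


def average_over_regions(region_embeddings: np.ndarray,
                         regions: np.ndarray) -> np.ndarray:
    """Mean embedding over a region set G (duplicate ids are deduplicated).

    ``region_embeddings`` is (N, ...) indexed by region id.
    """
    regions = np.unique(np.asarray(regions))
    if regions.size == 0:
        raise ValueError("empty region set")
    return np.asarray(region_embeddings)[regions].mean(axis=0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def embedding_shift(mean_g1: np.ndarray, mean_g2: np.ndarray) -> float:
    """1 - cosine similarity of two group-mean embeddings; in [0, 2]."""
    return 1.0 - cosine_similarity(mean_g1, mean_g2)


def pairwise_similarity_matrix(embeddings: np.ndarray) -> np.ndarray:
    """Symmetric cosine-similarity matrix of row vectors; unit diagonal."""
    X = np.asarray(embeddings, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("cosine similarity undefined for a zero vector")
    S = (X / norms[:, None]) @ (X / norms[:, None]).T
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def module_similarity_gap(similarity: np.ndarray, modules: np.ndarray,
                          n_permutations: int = 2000, seed: int = 0,
                          ) -> tuple[float, float]:
    """Within-module minus cross-module mean pairwise similarity, with a
    one-sided permutation p-value over regulator module labels."""
    modules = np.asarray(modules)
    M = modules.size
    iu = np.triu_indices(M, k=1)
    sims = similarity[iu]

    def gap(labels):
        same = labels[iu[0]] == labels[iu[1]]
        return sims[same].mean() - sims[~same].mean()

    observed = gap(modules)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if gap(rng.permutation(modules)) >= observed:
            count += 1
    pvalue = (count + 1) / (n_permutations + 1)
    return float(observed), float(pvalue)
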