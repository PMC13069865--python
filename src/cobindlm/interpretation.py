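"""Ranking candidate driver regulators from embedding shifts.

Regions are split into two outcome groups (e.g. increased vs. stable
expression); each regulator's embedding shift between the group means is
ranked, normalized to a [0, 1] ranking score, and optionally averaged across
modalities into a composite score whose top-k entries are called key
regulators.  Cofactors of a focal regulator are inferred from embedding
similarity over a region set, optionally with knockout-induced shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .encoding import CistromeCatalog, knockout
from .representations import (
    average_over_regions,
    cosine_similarity,
    embedding_shift,
)


@dataclass
class RegionGroups:
    """Two disjoint, nonempty region-id sets with the rule that produced them."""

    g1: np.ndarray   # changed / increased / causal
    g2: np.ndarray   # unchanged / stable / non-causal
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.g1 = np.unique(np.asarray(self.g1))
        self.g2 = np.unique(np.asarray(self.g2))
        if self.g1.size == 0 or self.g2.size == 0:
            side = "G1" if self.g1.size == 0 else "G2"
            raise ValueError(f"region group {side} is empty")
        if np.intersect1d(self.g1, self.g2).size:
            raise ValueError("region groups must be disjoint")


def group_by_expression_change(delta_log1p: np.ndarray) -> RegionGroups:
    """Increased: Δlog1p > 1; stable: −0.5 ≤ Δ ≤ 0.5; others excluded."""
    delta = np.asarray(delta_log1p, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("expression deltas must be finite")
    increased = np.flatnonzero(delta > 1.0)
    stable = np.flatnonzero((delta >= -0.5) & (delta <= 0.5))
    return RegionGroups(increased, stable, provenance={
        "rule": "expression_change", "increased": "delta > 1",
        "stable": "-0.5 <= delta <= 0.5"})


def group_by_accessibility_change(
    log2fc: np.ndarray, coverage_mask: np.ndarray,
    top_n_unchanged: int = 40000,
) -> RegionGroups:
    """Increased: log2FC > 2; unchanged: smallest |log2FC| among covered regions.

    ``top_n_unchanged`` defaults to the full-genome value of 40,000 and is
    clipped to min(top_n, 50% of covered regions) on small genomes.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    covered = np.asarray(coverage_mask, dtype=bool)
    increased = np.flatnonzero(log2fc > 2.0)
    candidates = np.flatnonzero(covered)
    n = min(top_n_unchanged, max(1, candidates.size // 2)) \
        if candidates.size < 2 * top_n_unchanged else top_n_unchanged
    order = candidates[np.argsort(np.abs(log2fc[candidates]), kind="stable")]
    unchanged = np.setdiff1d(order[:n], increased)
    return RegionGroups(increased, unchanged, provenance={
        "rule": "accessibility_change", "increased": "log2fc > 2",
        "top_n_unchanged": int(n)})


def rank_by_shift(
    region_regulator_embeddings: np.ndarray,
    groups: RegionGroups,
    regulator_ids: list[str],
) -> pd.DataFrame:
    """Rank regulators by embedding shift between the two group means.

    ``region_regulator_embeddings``: (N, M, d) per-region regulator-level
    embeddings.  Returns a frame (index: regulator) with columns ``shift``,
    ``rank`` (descending shift, average ranks on ties) and ``score``
    = 1 − (rank−1)/(M−1), sorted by rank then regulator id.
    """
    emb = np.asarray(region_regulator_embeddings)
    mean_g1 = average_over_regions(emb, groups.g1)   # (M, d)
    mean_g2 = average_over_regions(emb, groups.g2)
    shifts = np.array([embedding_shift(mean_g1[m], mean_g2[m])
                       for m in range(len(regulator_ids))])
    ranks = rankdata(-shifts, method="average")
    M = len(regulator_ids)
    scores = 1.0 - (ranks - 1.0) / (M - 1.0) if M > 1 else np.ones(1)
    df = pd.DataFrame({"shift": shifts, "rank": ranks, "score": scores},
                      index=pd.Index(regulator_ids, name="regulator"))
    return df.sort_index().sort_values("rank", kind="stable")


def composite_ranking(
    ranking_expr: pd.DataFrame, ranking_access: pd.DataFrame,
    k: int = 25, exclude: set[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Mean of two modality ranking scores; top-k are the key regulators.

    Regulators missing from either modality are excluded; ``exclude`` lists
    additional ids to drop (e.g. epigenetic-modification or accessibility
    cistromes, which are not candidate drivers).
    """
    common = ranking_expr.index.intersection(ranking_access.index)
    if common.empty:
        raise ValueError("ranking universes are disjoint")
    if exclude:
        common = common.difference(sorted(exclude))
    df = pd.DataFrame({
        "score_expr": ranking_expr.loc[common, "score"],
        "score_access": ranking_access.loc[common, "score"],
    })
    df["composite"] = df.mean(axis=1)
    df = df.sort_index().sort_values("composite", ascending=False, kind="stable")
    key = list(df.index[:k])
    return df, key


def celltype_specific_score(pairwise_scores: list[pd.Series]) -> pd.Series:
    """Mean composite score of one cell type over its pairings with all others."""
    if not pairwise_scores:
        raise ValueError("need at least one pairwise ranking")
    return pd.concat(pairwise_scores, axis=1).mean(axis=1)


def cofactor_inference(
    focal: str,
    region_regulator_embeddings: np.ndarray,
    regions: np.ndarray,
    regulator_ids: list[str],
    top_n: int = 30,
    knockout_inputs: dict | None = None,
) -> pd.DataFrame:
    """Rank potential cofactors of ``focal`` by embedding similarity.

    Similarity is the cosine between region-averaged regulator embeddings
    over ``regions``; the focal regulator itself is excluded.  When
    ``knockout_inputs`` is given (keys: ``model``, ``tokens``, ``catalog``,
    optionally ``regions``), each cofactor's embedding shift between the
    unperturbed and focal-knockout inputs is reported as well.
    """
    if focal not in regulator_ids:
        raise KeyError(f"focal regulator {focal!r} has no embedding")
    emb = np.asarray(region_regulator_embeddings)
    means = average_over_regions(emb, regions)          # (M, d)
    f = regulator_ids.index(focal)
    rows = []
    for m, r in enumerate(regulator_ids):
        if m == f:
            continue
        rows.append((r, cosine_similarity(means[f], means[m])))
    df = pd.DataFrame(rows, columns=["regulator", "similarity"]) \
           .sort_values(["similarity", "regulator"], ascending=[False, True]) \
           .set_index("regulator")

    if knockout_inputs is not None:
        from .representations import cistrome_embeddings, regulator_embedding
        model = knockout_inputs["model"]
        tokens = knockout_inputs["tokens"]
        catalog: CistromeCatalog = knockout_inputs["catalog"]
        sub = np.asarray(knockout_inputs.get("regions", regions))
        ko = knockout(tokens, focal, catalog)
        base_emb = regulator_embedding(
            cistrome_embeddings(model, tokens.tokens[sub], tokens.position_ids),
            catalog, regulator_ids)
        ko_emb = regulator_embedding(
            cistrome_embeddings(model, ko.tokens[sub], ko.position_ids),
            catalog, regulator_ids)
        base_mean = base_emb.mean(axis=0)
        ko_mean = ko_emb.mean(axis=0)
        shifts = {r: embedding_shift(base_mean[m], ko_mean[m])
                  for m, r in enumerate(regulator_ids) if r != focal}
        df["knockout_shift"] = pd.Series(shifts)
    return df.head(top_n) if top_n is not None else df
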