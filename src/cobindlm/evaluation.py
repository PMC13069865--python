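"""Benchmark plumbing: candidate-peak baseline, cell-type-specific site
definitions, and ranking metrics.

The baseline scores a regulator's binding per bin as candidate-peak presence
times chromatin-accessibility signal.  Cell-type-specific binding sites are
bins where ChIP signal is present in one cell type and absent in the other
while accessibility stays matched; pairs with too few events or a strongly
imbalanced present/absent ratio are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

logger = logging.getLogger(__name__)

PSEUDO_COUNT = 0.1

CHIP_MIN_SIGNAL = 3.0       # strict: signal must exceed 3
CHIP_MIN_FOLD = 3.0         # inclusive: at least 3-fold higher
ACC_MAX_ABS_LOG2FC = 0.5    # strict: |log2 fold change| < 0.5
ACC_MIN_SIGNAL = 3.0        # strict: accessibility must exceed 3
MIN_SPECIFIC_EVENTS = 50
MAX_IMBALANCE_FOLD = 5.0


def baseline_score(candidate_mask: np.ndarray,
                   accessibility: np.ndarray) -> np.ndarray:
    """Elementwise product of the candidate-peak mask with accessibility."""
    mask = np.asarray(candidate_mask)
    acc = np.asarray(accessibility, dtype=float)
    if mask.shape != acc.shape:
        raise ValueError("candidate mask and accessibility lengths differ")
    return mask * acc


def candidate_peaks(
    regulator: str,
    catalog,
    peak_bins: dict[str, np.ndarray],
    n_bins: int,
    motif_bins: np.ndarray | None = None,
    exclude_cistrome: str | None = None,
    min_cistromes: int = 5,
) -> np.ndarray:
    """Binary candidate-peak mask for one regulator.

    With at least ``min_cistromes`` cistromes available (excluding the test
    cistrome) the mask is the union of their peak bins; otherwise the
    supplied motif-bin mask is used.
    """
    cols = catalog.columns_of(regulator)
    cids = [catalog.cistrome_ids[i] for i in cols if
            catalog.cistrome_ids[i] != exclude_cistrome]
    if len(cids) >= min_cistromes:
        mask = np.zeros(n_bins, dtype=int)
        for cid in cids:
            mask[np.asarray(peak_bins[cid])] = 1
        return mask
    if motif_bins is None:
        raise ValueError(
            f"{regulator}: fewer than {min_cistromes} cistromes and no motif mask")
    mask = np.zeros(n_bins, dtype=int)
    mask[np.asarray(motif_bins)] = 1
    return mask


def normalize_to_background(signal: np.ndarray) -> np.ndarray:
    """Scale a signal track by its genome-wide mean read density."""
    signal = np.asarray(signal, dtype=float)
    mean = signal.mean()
    if mean == 0:
        return signal
    return signal / mean


@dataclass
class PairResult:
    """Specific-site calls for one cistrome pair plus pair-level validity."""

    calls: pd.DataFrame
    accepted: bool
    reason: str = ""


def specific_sites(
    chip_a: np.ndarray, chip_b: np.ndarray,
    acc_a: np.ndarray, acc_b: np.ndarray,
    pseudo_count: float = PSEUDO_COUNT,
) -> PairResult:
    """Call cell-type-specific binding sites between two matched cistromes.

    A bin is A-specific iff chip_A > 3, chip_A/chip_B >= 3,
    |log2(acc_A/acc_B)| < 0.5, and both accessibility signals exceed 3
    (symmetric for B).  Zero denominators use a pseudo-count (logged).  The
    pair is rejected when fewer than 50 specific events exist or the
    present/absent imbalance reaches 5-fold.
    """
    chip_a, chip_b, acc_a, acc_b = (np.asarray(x, dtype=float)
                                    for x in (chip_a, chip_b, acc_a, acc_b))
    if not (chip_a.shape == chip_b.shape == acc_a.shape == acc_b.shape):
        raise ValueError("signal vectors must share one length")
    n_zero = int((chip_b == 0).sum() + (chip_a == 0).sum()
                 + (acc_a == 0).sum() + (acc_b == 0).sum())
    if n_zero:
        logger.info("pseudo-count %.2g applied to %d zero signals",
                    pseudo_count, n_zero)
    ca = np.where(chip_a == 0, pseudo_count, chip_a)
    cb = np.where(chip_b == 0, pseudo_count, chip_b)
    aa = np.where(acc_a == 0, pseudo_count, acc_a)
    ab = np.where(acc_b == 0, pseudo_count, acc_b)

    acc_matched = (np.abs(np.log2(aa / ab)) < ACC_MAX_ABS_LOG2FC) \
        & (acc_a > ACC_MIN_SIGNAL) & (acc_b > ACC_MIN_SIGNAL)
    a_specific = (chip_a > CHIP_MIN_SIGNAL) & (ca / cb >= CHIP_MIN_FOLD) & acc_matched
    b_specific = (chip_b > CHIP_MIN_SIGNAL) & (cb / ca >= CHIP_MIN_FOLD) & acc_matched

    calls = pd.DataFrame({
        "chip_a": chip_a, "chip_b": chip_b,
        "acc_a": acc_a, "acc_b": acc_b,
        "a_specific": a_specific, "b_specific": b_specific,
    })
    n_a, n_b = int(a_specific.sum()), int(b_specific.sum())
    total = n_a + n_b
    if total < MIN_SPECIFIC_EVENTS:
        return PairResult(calls, False, f"only {total} specific events (<{MIN_SPECIFIC_EVENTS})")
    lo, hi = sorted((max(n_a, 1), max(n_b, 1)))
    if hi / lo >= MAX_IMBALANCE_FOLD:
        return PairResult(calls, False,
                          f"present/absent imbalance {hi}/{lo} >= {MAX_IMBALANCE_FOLD}-fold")
    return PairResult(calls, True)


def metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """AUROC (rank-based) and AUPRC (trapezoidal over the PR curve)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("metrics undefined for single-class labels")
    auroc = float(roc_auc_score(labels, scores))
    precision, recall, _ = precision_recall_curve(labels, scores)
    # trapezoidal area along the threshold-ordered curve (ties give zero-width
    # segments rather than spurious interpolation)
    auprc = float(auc(recall, precision))
    return {"auroc": auroc, "auprc": auprc}
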