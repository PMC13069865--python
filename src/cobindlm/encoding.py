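"""Binding-status encoding of cistrome signal tracks.

A cistrome's genome-wide signal (mean RPM per 1-kb bin) is discretized into
five ordinal binding statuses.  The binding/non-binding threshold is the 10th
percentile of signals at bins carrying a called peak for that cistrome; the
binding set is split into signal tertiles (slightly / moderately / strongly
positive) and the non-binding set at its median (strongly / slightly
negative).  This module also applies the catalog-level quality filters and
implements the in-silico knockout and omission perturbations of the token
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordinal status names, ascending; token ids 0..4 index this list.
VOCABULARY = (
    "strongly negative",
    "slightly negative",
    "slightly positive",
    "moderately positive",
    "strongly positive",
)
MASK_TOKEN_ID = 5
VOCAB_SIZE = 6  # five statuses + [MASK]

#: QC metric -> minimal passing value (median quality score, uniquely mapped
#: ratio, PCR bottleneck coefficient, fraction of reads in peaks, number of
#: 10-fold confident peaks).
QC_THRESHOLDS = {
    "median_quality": 25.0,
    "mapped_ratio": 0.60,
    "pbc": 0.80,
    "frip": 0.01,
    "confident_peaks": 500.0,
}
MIN_QC_PASSED = 4
TF_MIN_PEAKS = 100       # strict: "more than 100"
OTHER_MIN_PEAKS = 1000
MIN_GENOME_COVERAGE = 0.60


class CistromeCatalog:
    """Metadata table mapping cistromes to regulators, cell types, and QC.

    Wraps a :class:`pandas.DataFrame` with one row per cistrome.  Required
    columns: ``cistrome_id``, ``regulator``, ``cell_type``, ``assay_class``
    (one of ``tf`` / ``histone`` / ``accessibility``).  QC columns are only
    needed by :func:`qc_filter`.
    """

    REQUIRED = ("cistrome_id", "regulator", "cell_type", "assay_class")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        if table["cistrome_id"].duplicated().any():
            raise ValueError("cistrome_id values must be unique")
        self.table = table.reset_index(drop=True)

    def __len__(self):
        return len(self.table)

    @property
    def cistrome_ids(self) -> list[str]:
        return list(self.table["cistrome_id"])

    @property
    def regulators(self) -> list[str]:
        return sorted(self.table["regulator"].unique())

    def columns_of(self, regulator: str) -> np.ndarray:
        """Column indices (cistrome order) belonging to one regulator."""
        idx = np.flatnonzero((self.table["regulator"] == regulator).to_numpy())
        if idx.size == 0:
            raise KeyError(
                f"unknown regulator {regulator!r}; valid ids: {self.regulators}")
        return idx

    def grouping_matrix(self, regulators: list[str] | None = None) -> np.ndarray:
        """(M, P) row-stochastic matrix averaging cistrome columns per regulator."""
        regs = regulators if regulators is not None else self.regulators
        G = np.zeros((len(regs), len(self.table)))
        for m, r in enumerate(regs):
            cols = self.columns_of(r)
            G[m, cols] = 1.0 / cols.size
        return G

    def assay_class_of(self, regulator: str) -> str:
        return str(self.table.iloc[self.columns_of(regulator)[0]]["assay_class"])

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CistromeCatalog":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class BinnedSignalMatrix:
    """Regions x cistromes mean-signal matrix over consecutive 1-kb bins."""

    values: np.ndarray            # (N, P) non-negative reals
    chroms: np.ndarray            # (N,) chromosome names
    starts: np.ndarray            # (N,) 0-based start
    ends: np.ndarray              # (N,) half-open end
    cistrome_ids: list[str]
    peak_mask: np.ndarray | None = None   # (N, P) bool, peak presence per bin

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("signal values must be finite and non-negative")
        widths = np.asarray(self.ends) - np.asarray(self.starts)
        if widths.size and not (widths == widths[0]).all():
            raise ValueError("all regions must share one bin size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_cistromes(self) -> int:
        return self.values.shape[1]


@dataclass
class TokenMatrix:
    """Regions x cistromes binding-status tokens in {0..4}.

    ``position_ids`` records each column's index in the original (pre-omission)
    cistrome ordering so position embeddings stay aligned after columns are
    removed.
    """

    tokens: np.ndarray                    # (N, P) int8 in {0..4}
    cistrome_ids: list[str]
    position_ids: np.ndarray | None = None
    vocabulary: tuple = VOCABULARY

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int8)
        if self.tokens.min(initial=0) < 0 or self.tokens.max(initial=0) > 4:
            raise ValueError("tokens must lie in {0..4}")
        if self.position_ids is None:
            self.position_ids = np.arange(self.tokens.shape[1])
        self.position_ids = np.asarray(self.position_ids)

    @property
    def n_regions(self) -> int:
        return self.tokens.shape[0]

    @property
    def n_cistromes(self) -> int:
        return self.tokens.shape[1]


# ---------------------------------------------------------------------------
# catalog QC
# ---------------------------------------------------------------------------

def combined_qc_score(row: pd.Series) -> float:
    """Combined QC score: sum of metric values scaled by their thresholds."""
    if "combined_score" in row and pd.notna(row.get("combined_score")):
        return float(row["combined_score"])
    return float(sum(row[m] / t for m, t in QC_THRESHOLDS.items()))


def qc_filter(catalog: CistromeCatalog) -> CistromeCatalog:
    """Apply the catalog quality filters and per-(regulator, cell label) dedup.

    A cistrome is retained when it (1) passes at least four of the five QC
    metric thresholds, (2) has more than 100 called peaks for transcription
    factors or more than 1,000 for other regulator classes, and (3) covers
    more than 60% of non-peak regions with reads.  Among retained cistromes
    sharing a (regulator, cell label), only the one with the highest combined
    QC score is kept.
    """
    df = catalog.table
    keep_rows, skipped = [], 0
    for _, row in df.iterrows():
        try:
            passed = sum(float(row[m]) >= t for m, t in QC_THRESHOLDS.items())
            n_peaks = float(row["peak_count"])
            coverage = float(row["genome_coverage"])
        except (KeyError, TypeError, ValueError):
            skipped += 1
            logger.warning("cistrome %s skipped: missing QC metric",
                           row.get("cistrome_id", "?"))
            continue
        if passed < MIN_QC_PASSED:
            continue
        min_peaks = TF_MIN_PEAKS if row["assay_class"] == "tf" else OTHER_MIN_PEAKS
        if not n_peaks > min_peaks:
            continue
        if not coverage > MIN_GENOME_COVERAGE:
            continue
        keep_rows.append(row)
    if skipped:
        logger.warning("%d cistromes skipped for missing metrics", skipped)
    if not keep_rows:
        return CistromeCatalog(df.iloc[0:0])
    kept = pd.DataFrame(keep_rows)
    kept["_score"] = kept.apply(combined_qc_score, axis=1)
    kept = (kept.sort_values(["_score", "cistrome_id"], ascending=[False, True])
                .drop_duplicates(subset=["regulator", "cell_type"], keep="first")
                .sort_index()
                .drop(columns="_score"))
    return CistromeCatalog(kept)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _bin_intervals(df: pd.DataFrame, bin_size: int, n_bins: dict) -> dict:
    """Per-chromosome boolean peak-presence over fixed tiles."""
    out = {c: np.zeros(n, dtype=bool) for c, n in n_bins.items()}
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom not in out:
            continue
        b0 = int(start) // bin_size
        b1 = (int(end) - 1) // bin_size
        out[chrom][b0:min(b1 + 1, n_bins[chrom])] = True
    return out


def bin_and_filter(
    tracks: dict[str, pd.DataFrame],
    peaks: dict[str, pd.DataFrame],
    blacklist: pd.DataFrame | None = None,
    bin_size: int = 1000,
    min_peak_cistromes: int = 2,
) -> BinnedSignalMatrix:
    """Tile the genome into fixed bins, average signal, and filter bins.

    ``tracks`` maps cistrome id to a bedGraph-like frame (chrom/start/end/value);
    ``peaks`` maps cistrome id to a BED-like frame.  Bins overlapping the
    blacklist are removed, and only bins with peak presence in more than
    ``min_peak_cistromes`` cistromes are retained (strict inequality).
    """
    cistrome_ids = sorted(tracks)
    if sorted(peaks) != cistrome_ids:
        raise ValueError("tracks and peaks must cover the same cistromes")

    # chromosome extents from the union of tracks and peaks
    extent: dict[str, int] = {}
    for df in list(tracks.values()) + list(peaks.values()):
        for chrom, end in zip(df["chrom"], df["end"]):
            extent[chrom] = max(extent.get(chrom, 0), int(end))
    n_bins = {c: int(np.ceil(e / bin_size)) for c, e in sorted(extent.items())}

    chrom_order = sorted(n_bins)
    values = {c: np.zeros((n_bins[c], len(cistrome_ids))) for c in chrom_order}
    peak_presence = {c: np.zeros((n_bins[c], len(cistrome_ids)), dtype=bool)
                     for c in chrom_order}

    for j, cid in enumerate(cistrome_ids):
        df = tracks[cid]
        for chrom, start, end, val in zip(df["chrom"], df["start"], df["end"], df["value"]):
            start, end = int(start), int(end)
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                values[chrom][b, j] += float(val) * (hi - lo) / bin_size
        pmask = _bin_intervals(peaks[cid], bin_size, n_bins)
        for c in chrom_order:
            peak_presence[c][:, j] = pmask[c]

    black = (_bin_intervals(blacklist, bin_size, n_bins)
             if blacklist is not None else {c: np.zeros(n_bins[c], bool) for c in chrom_order})

    rows_v, rows_p, rows_chrom, rows_start = [], [], [], []
    for c in chrom_order:
        n_with_peak = peak_presence[c].sum(axis=1)
        keep = (n_with_peak > min_peak_cistromes) & ~black[c]
        idx = np.flatnonzero(keep)
        rows_v.append(values[c][idx])
        rows_p.append(peak_presence[c][idx])
        rows_chrom.extend([c] * idx.size)
        rows_start.extend(idx * bin_size)
    if not rows_chrom:
        raise ValueError("no bins retained after filtering (empty matrix)")
    starts = np.asarray(rows_start)
    return BinnedSignalMatrix(
        values=np.vstack(rows_v),
        chroms=np.asarray(rows_chrom, dtype=object),
        starts=starts,
        ends=starts + bin_size,
        cistrome_ids=cistrome_ids,
        peak_mask=np.vstack(rows_p),
    )


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _equal_portions(order: np.ndarray, n_chunks: int, first_token: int) -> np.ndarray:
    """Assign ascending tokens to chunks of an ordering; sizes differ by <=1.

    Extra elements go to the earlier (lower-signal) chunks, matching
    ``np.array_split`` semantics.
    """
    tokens = np.empty(order.size, dtype=np.int8)
    for t, chunk in enumerate(np.array_split(order, n_chunks)):
        tokens[chunk] = first_token + t
    return tokens


def discretize(
    signals: np.ndarray,
    peak_bins: np.ndarray | None = None,
    percentile_method: str = "linear",
    peak_signals: np.ndarray | None = None,
) -> np.ndarray:
    """Discretize one cistrome's binned signals into the five statuses.

    The binding threshold is the 10th percentile of signals at ``peak_bins``
    (linear interpolation between order statistics by default); ``peak_signals``
    may supply the peak-bin signal values directly instead.  Bins with
    signal >= threshold are "binding" and are split into signal tertiles
    (tokens 2/3/4); the rest are "non-binding" and are split at their median
    (tokens 0/1).  Ties are broken by (signal, bin index) lexicographic order
    so the equal-portion size property holds exactly.
    """
    signals = np.asarray(signals, dtype=float)
    if peak_signals is None:
        peak_bins = np.asarray(peak_bins) if peak_bins is not None else np.array([])
        if peak_bins.size == 0:
            raise ValueError("empty peak_bins: binding threshold undefined; "
                             "cistrome rejected")
        peak_signals = signals[peak_bins]
    peak_signals = np.asarray(peak_signals, dtype=float)
    threshold = np.percentile(peak_signals, 10, method=percentile_method)

    tokens = np.empty(signals.size, dtype=np.int8)
    binding = signals >= threshold
    for mask, n_chunks, first in ((~binding, 2, 0), (binding, 3, 2)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        order = idx[np.lexsort((idx, signals[idx]))]
        # order is positions sorted by (signal, index); map chunk ranks back
        chunk_tokens = _equal_portions(np.arange(order.size), n_chunks, first)
        tokens[order] = chunk_tokens
    return tokens


def encode_matrix(matrix: BinnedSignalMatrix,
                  peak_bins: dict[str, np.ndarray] | None = None) -> TokenMatrix:
    """Discretize every cistrome column of a signal matrix.

    ``peak_bins`` maps cistrome id to row indices with peak presence; if
    omitted, the matrix's own ``peak_mask`` is used.
    """
    N, P = matrix.values.shape
    tokens = np.empty((N, P), dtype=np.int8)
    for j, cid in enumerate(matrix.cistrome_ids):
        if peak_bins is not None:
            pb = np.asarray(peak_bins[cid])
        elif matrix.peak_mask is not None:
            pb = np.flatnonzero(matrix.peak_mask[:, j])
        else:
            raise ValueError("peak_bins required when matrix has no peak_mask")
        tokens[:, j] = discretize(matrix.values[:, j], pb)
    return TokenMatrix(tokens=tokens, cistrome_ids=list(matrix.cistrome_ids))


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def knockout(tokens: TokenMatrix, regulator: str,
             catalog: CistromeCatalog) -> TokenMatrix:
    """In-silico knockout: set all non-"strongly negative" statuses to 0.

    Applies to every cistrome of ``regulator``; idempotent.
    """
    cols = catalog.columns_of(regulator)
    new = tokens.tokens.copy()
    block = new[:, cols]
    block[block > 0] = 0
    new[:, cols] = block
    return replace(tokens, tokens=new,
                   cistrome_ids=list(tokens.cistrome_ids),
                   position_ids=tokens.position_ids.copy())


def omit(tokens: TokenMatrix, regulator: str,
         catalog: CistromeCatalog) -> tuple[TokenMatrix, CistromeCatalog]:
    """Remove all cistrome columns of one regulator.

    Remaining columns keep their original position ids so pre-trained
    position embeddings still align.
    """
    cols = catalog.columns_of(regulator)
    keep = np.setdiff1d(np.arange(tokens.n_cistromes), cols)
    new_tokens = TokenMatrix(
        tokens=tokens.tokens[:, keep],
        cistrome_ids=[tokens.cistrome_ids[i] for i in keep],
        position_ids=tokens.position_ids[keep],
    )
    new_catalog = CistromeCatalog(
        catalog.table[catalog.table["regulator"] != regulator])
    return new_tokens, new_catalog
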