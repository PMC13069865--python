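"""Synthetic cistrome catalogs with planted regulatory structure.

The generator emulates the statistical skeleton of a large cistrome
compendium: regulators are partitioned into latent co-binding modules; in
each 1-kb region a module is either active or not; cistromes of regulators
in active modules bind with high probability while background binding is
rare.  Bound bins receive log-normal signal, unbound bins small half-normal
noise, and downstream labels are causally driven by a planted subset of
"driver" regulators.  Because the structure is known exactly, every model
component has a ground-truth test surface.

Default parameters are fixed study conditions chosen so the planted
co-binding grammar is statistically recoverable at desk scale (see
docs/methods.md for the identifiability argument).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import BinnedSignalMatrix, CistromeCatalog

CHROM = "chrS"  # the synthetic genome: one chromosome of consecutive 1-kb bins
BIN_SIZE = 1000

# fixed offsets deriving one RNG stream per artifact from the master seed,
# so regenerating labels does not perturb the matrix
_STREAM_CATALOG = 0
_STREAM_MATRIX = 1
_STREAM_LABELS = 2
_STREAM_PAIR = 3


@dataclass
class SyntheticConfig:
    n_regulators: int = 32
    cistromes_per_regulator: int = 2
    n_modules: int = 4
    n_regions: int = 5000
    module_activity_rate: float = 0.6
    within_module_bind_prob: float = 0.9
    background_bind_prob: float = 0.05
    signal_location: float = 10.0   # median bound signal, RPM-like units
    signal_scale: float = 0.5       # sigma of the underlying normal
    n_drivers: int = 4
    #: sample at most one driver per module (requires n_drivers <= n_modules);
    #: keeps the causal signal attributable to individual regulators instead
    #: of being absorbed by a doubly-driven module's co-binding
    spread_drivers: bool = False
    label_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        probs = (self.module_activity_rate, self.within_module_bind_prob,
                 self.background_bind_prob)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_drivers > self.n_regulators:
            raise ValueError("n_drivers cannot exceed n_regulators")
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if self.spread_drivers and self.n_drivers > self.n_modules:
            raise ValueError("spread_drivers requires n_drivers <= n_modules")
        if self.cistromes_per_regulator < 1:
            raise ValueError("need at least one cistrome per regulator")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PlantedTruth:
    module_of_regulator: dict[str, int]
    driver_set: set[str]
    region_module_activity: np.ndarray   # (n_regions, n_modules) bool

    def module_array(self, regulators: list[str]) -> np.ndarray:
        return np.array([self.module_of_regulator[r] for r in regulators])


@dataclass
class PeakSet:
    """Peak records of a synthetic matrix: one record per bound (bin, cistrome)."""

    bound_mask: np.ndarray          # (n_regions, n_cistromes) bool
    cistrome_ids: list[str]

    def bins_of(self, cistrome_id: str) -> np.ndarray:
        j = self.cistrome_ids.index(cistrome_id)
        return np.flatnonzero(self.bound_mask[:, j])

    @property
    def n_peaks(self) -> int:
        return int(self.bound_mask.sum())

    def to_bed(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.bound_mask)
        return pd.DataFrame({
            "chrom": CHROM,
            "start": rows * BIN_SIZE,
            "end": rows * BIN_SIZE + BIN_SIZE,
            "name": [self.cistrome_ids[j] for j in cols],
        })


def regulator_ids(config: SyntheticConfig) -> list[str]:
    width = len(str(config.n_regulators - 1))
    return [f"TF{str(i).zfill(width)}" for i in range(config.n_regulators)]


def generate_catalog(config: SyntheticConfig) -> tuple[CistromeCatalog, PlantedTruth]:
    """Catalog of ``n_regulators x cistromes_per_regulator`` synthetic cistromes.

    Module assignment is round-robin (regulator i -> module i mod K) so tiny
    configs get balanced modules; the driver set is sampled without
    replacement from the master seed's catalog stream, which also fixes the
    per-region module-activity pattern.
    """
    regs = regulator_ids(config)
    rng = config.rng(_STREAM_CATALOG)
    module_of = {r: i % config.n_modules for i, r in enumerate(regs)}
    if config.spread_drivers:
        chosen_modules = rng.choice(config.n_modules, size=config.n_drivers,
                                    replace=False)
        drivers = set()
        for k in chosen_modules:
            members = [r for r in regs if module_of[r] == k]
            drivers.add(str(rng.choice(members)))
    else:
        drivers = set(rng.choice(regs, size=config.n_drivers, replace=False))
    activity = rng.random((config.n_regions, config.n_modules)) < config.module_activity_rate

    rows = []
    for r in regs:
        for k in range(config.cistromes_per_regulator):
            rows.append({
                "cistrome_id": f"{r}_ct{k}",
                "regulator": r,
                "cell_type": f"cell_{k}",
                "assay_class": "tf",
                "median_quality": 30.0,
                "mapped_ratio": 0.9,
                "pbc": 0.9,
                "frip": 0.05,
                "confident_peaks": 2000.0,
                "peak_count": 5000.0,
                "genome_coverage": 0.8,
            })
    catalog = CistromeCatalog(pd.DataFrame(rows))
    truth = PlantedTruth(module_of_regulator=module_of, driver_set=drivers,
                         region_module_activity=activity)
    return catalog, truth


def _bound_mask(catalog: CistromeCatalog, truth: PlantedTruth,
                config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    regs = catalog.table["regulator"].to_numpy()
    module_cols = np.array([truth.module_of_regulator[r] for r in regs])
    active = truth.region_module_activity[:, module_cols]   # (N, P)
    p = np.where(active, config.within_module_bind_prob, config.background_bind_prob)
    return rng.random(p.shape) < p


def generate_signal_matrix(
    catalog: CistromeCatalog, truth: PlantedTruth, config: SyntheticConfig,
) -> tuple[BinnedSignalMatrix, PeakSet]:
    """Sample the regions x cistromes signal matrix and its peak records.

    Bound entries draw log-normal signal (median ``signal_location``); unbound
    entries draw half-normal noise with scale 5% of ``signal_location``.
    """
    rng = config.rng(_STREAM_MATRIX)
    bound = _bound_mask(catalog, truth, config, rng)
    signal = rng.lognormal(np.log(config.signal_location), config.signal_scale,
                           size=bound.shape)
    noise = np.abs(rng.normal(0.0, 0.05 * config.signal_location, size=bound.shape))
    values = np.where(bound, signal, noise)
    starts = np.arange(config.n_regions) * BIN_SIZE
    matrix = BinnedSignalMatrix(
        values=values,
        chroms=np.full(config.n_regions, CHROM, dtype=object),
        starts=starts,
        ends=starts + BIN_SIZE,
        cistrome_ids=catalog.cistrome_ids,
        peak_mask=bound,
    )
    return matrix, PeakSet(bound_mask=bound, cistrome_ids=catalog.cistrome_ids)


def driver_score(truth: PlantedTruth, peaks: PeakSet,
                 catalog: CistromeCatalog) -> np.ndarray:
    """Latent per-region score: driver binding indicators averaged per regulator."""
    if not truth.driver_set:
        raise ValueError("driver_set is empty: labels undefined for this task")
    score = np.zeros(peaks.bound_mask.shape[0])
    for r in sorted(truth.driver_set):
        cols = catalog.columns_of(r)
        score += peaks.bound_mask[:, cols].mean(axis=1)
    return score


def generate_region_labels(
    truth: PlantedTruth, peaks: PeakSet, task: str,
    config: SyntheticConfig, catalog: CistromeCatalog,
) -> np.ndarray:
    """Region labels causally driven by the planted drivers.

    ``task="continuous"`` returns the noisy latent score; ``task="binary"``
    thresholds it at its median.
    """
    if task not in ("binary", "continuous"):
        raise ValueError(f"unknown task {task!r}")
    rng = config.rng(_STREAM_LABELS)
    score = driver_score(truth, peaks, catalog)
    score = score + rng.normal(0.0, config.label_noise_sd, size=score.size)
    if task == "continuous":
        return score
    return (score > np.median(score)).astype(int)


@dataclass
class CellTypePair:
    """Two matrices sharing background structure plus per-region change scores."""

    catalog: CistromeCatalog
    truth: PlantedTruth
    matrix_a: BinnedSignalMatrix
    matrix_b: BinnedSignalMatrix
    peaks_a: PeakSet
    peaks_b: PeakSet
    delta_labels: np.ndarray
    delta_regions: np.ndarray


def generate_celltype_pair(
    config: SyntheticConfig,
    delta_drivers: set[str],
    n_delta_regions: int | None = None,
) -> CellTypePair:
    """Matched pair of cell states: in B, ``delta_drivers`` gain binding in a
    designated region subset; ``delta_labels`` is the per-region noiseless
    change score driven by those gains.
    """
    if not delta_drivers:
        raise ValueError("delta_drivers must be non-empty")
    catalog, truth = generate_catalog(config)
    unknown = set(delta_drivers) - set(regulator_ids(config))
    if unknown:
        raise ValueError(f"delta_drivers not in regulator set: {sorted(unknown)}")
    matrix_a, peaks_a = generate_signal_matrix(catalog, truth, config)

    rng = config.rng(_STREAM_PAIR)
    if n_delta_regions is None:
        n_delta_regions = config.n_regions // 10
    delta_regions = np.sort(rng.choice(config.n_regions, size=n_delta_regions,
                                       replace=False))

    bound_b = peaks_a.bound_mask.copy()
    values_b = matrix_a.values.copy()
    for r in sorted(delta_drivers):
        cols = catalog.columns_of(r)
        for j in cols:
            gain = delta_regions[~bound_b[delta_regions, j]]
            bound_b[gain, j] = True
            values_b[gain, j] = rng.lognormal(
                np.log(config.signal_location), config.signal_scale, size=gain.size)

    matrix_b = BinnedSignalMatrix(
        values=values_b, chroms=matrix_a.chroms, starts=matrix_a.starts,
        ends=matrix_a.ends, cistrome_ids=catalog.cistrome_ids, peak_mask=bound_b)
    peaks_b = PeakSet(bound_mask=bound_b, cistrome_ids=catalog.cistrome_ids)

    delta = np.zeros(config.n_regions)
    for r in sorted(delta_drivers):
        cols = catalog.columns_of(r)
        delta += (bound_b[:, cols].mean(axis=1) - peaks_a.bound_mask[:, cols].mean(axis=1))
    return CellTypePair(catalog, truth, matrix_a, matrix_b, peaks_a, peaks_b,
                        delta, delta_regions)
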