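"""Bivalent and super-bivalent promoter classification.

The procedure, per sample:

1. H3K4me3 RPKM in 10-kb TSS-centred promoters, standardised to a z-score
   across all annotated genes (population SD).
2. The housekeeping baseline: the mean z of a curated housekeeping set.
3. The bivalent universe: either a supplied fixed gene list (when replicating
   an external bivalent catalogue) or genes with both H3K4me3 and H3K27me3
   RPKM above thresholds in a narrower (+/- 2.5 kb) promoter window.
4. Super-bivalent genes: bivalent genes whose H3K4me3 z-score is strictly
   higher than the housekeeping baseline AND whose H3K27me3 10-kb promoter
   RPKM is strictly greater than a fixed cutoff (default 1.0).

Both super-bivalency conditions are strict inequalities, so ties with the
baseline or the cutoff are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chip_quant import EnrichmentMatrix

log = logging.getLogger(__name__)


@dataclass
class ZScoredVector:
    """Raw RPKM alongside its per-sample z-standardisation."""

    raw: pd.Series
    z: pd.Series
    mean_raw: float
    sd_raw: float

    @property
    def row_ids(self) -> list[str]:
        return list(self.raw.index)


def zscore(values: pd.Series) -> ZScoredVector:
    """Standardise to mean 0, SD 1 (population SD, ddof=0).

    A constant vector has no spread to standardise; it maps to all zeros with
    a warning rather than an error so degenerate toy inputs stay usable.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ValueError("z-score needs at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        warnings.warn("z-score of a constant vector: returning all zeros", stacklevel=2)
        z = pd.Series(np.zeros(len(values)), index=values.index)
    else:
        z = (values - mean) / sd
    return ZScoredVector(values, z, mean, sd)


def housekeeping_baseline(zvec: ZScoredVector, hk_ids: Iterable[str]) -> float:
    """Mean z-score of the housekeeping genes — the super-bivalency bar."""
    hk_ids = list(hk_ids)
    if not hk_ids:
        raise ValueError("empty housekeeping set")
    missing = [g for g in hk_ids if g not in zvec.z.index]
    if missing:
        raise KeyError(f"housekeeping gene(s) absent from z-scored vector: {missing}")
    return float(zvec.z.loc[hk_ids].mean())


def call_bivalent(
    k4_matrix: EnrichmentMatrix,
    k27_matrix: EnrichmentMatrix,
    sample: str,
    k4_min_rpkm: float = 1.0,
    k27_min_rpkm: float = 1.0,
    fixed_set: Iterable[str] | None = None,
) -> set[str]:
    """Derive (or adopt) the bivalent gene universe for one sample.

    With ``fixed_set`` given, the externally defined universe is returned
    intersected with the annotated rows; otherwise genes carrying both marks
    at or above the RPKM thresholds in the supplied promoter matrices.
    """
    if list(k4_matrix.values.index) != list(k27_matrix.values.index):
        raise ValueError("H3K4me3 and H3K27me3 matrices have mismatched row universes")
    universe = set(k4_matrix.row_ids)
    if fixed_set is not None:
        fixed = set(fixed_set)
        kept = fixed & universe
        log.info("bivalent universe fixed externally: %d of %d in annotation", len(kept), len(fixed))
        return kept
    k4 = k4_matrix.sample(sample)
    k27 = k27_matrix.sample(sample)
    called = set(k4.index[(k4 >= k4_min_rpkm) & (k27 >= k27_min_rpkm)])
    log.info("sample %s: %d bivalent genes at thresholds (K4>=%g, K27>=%g)",
             sample, len(called), k4_min_rpkm, k27_min_rpkm)
    return called


@dataclass
class BivalencyCallSet:
    """Per-sample bivalency calls with the thresholds that produced them."""

    sample_id: str
    bivalent_genes: frozenset[str]
    super_bivalent_genes: frozenset[str]
    hk_baseline_z: float
    k27_cutoff_rpkm: float = 1.0
    thresholds_used: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.super_bivalent_genes <= self.bivalent_genes:
            raise ValueError("super-bivalent set must be a subset of the bivalent set")


def call_super_bivalent(
    bivalent_set: Iterable[str],
    k4_10kb_zvec: ZScoredVector,
    hk_baseline: float,
    k27_10kb_rpkm: pd.Series,
    cutoff: float = 1.0,
    sample_id: str = "sample",
) -> BivalencyCallSet:
    """Super-bivalent = bivalent AND K4 z > housekeeping baseline AND K27 RPKM > cutoff."""
    bivalent = frozenset(bivalent_set)
    missing = [g for g in bivalent if g not in k4_10kb_zvec.z.index or g not in k27_10kb_rpkm.index]
    if missing:
        raise KeyError(f"bivalent gene(s) absent from enrichment vectors: {sorted(missing)[:10]}")
    genes = sorted(bivalent)
    z = k4_10kb_zvec.z.loc[genes]
    k27 = k27_10kb_rpkm.loc[genes]
    super_set = frozenset(np.array(genes)[(z.to_numpy() > hk_baseline) & (k27.to_numpy() > cutoff)])
    return BivalencyCallSet(
        sample_id=sample_id,
        bivalent_genes=bivalent,
        super_bivalent_genes=super_set,
        hk_baseline_z=float(hk_baseline),
        k27_cutoff_rpkm=float(cutoff),
        thresholds_used={"hk_baseline_z": float(hk_baseline), "k27_cutoff_rpkm": float(cutoff)},
    )


def classify_sample(
    sample_id: str,
    k4_10kb: EnrichmentMatrix,
    k27_10kb: EnrichmentMatrix,
    k4_narrow: EnrichmentMatrix,
    k27_narrow: EnrichmentMatrix,
    hk_ids: Sequence[str],
    k4_min_rpkm: float = 1.0,
    k27_min_rpkm: float = 1.0,
    k27_cutoff: float = 1.0,
    fixed_bivalent: Iterable[str] | None = None,
) -> tuple[BivalencyCallSet, ZScoredVector]:
    """End-to-end bivalency classification of one sample.

    Returns the call set and the z-scored 10-kb H3K4me3 vector it was built
    from (useful for reporting and plotting).
    """
    zvec = zscore(k4_10kb.sample(sample_id))
    baseline = housekeeping_baseline(zvec, hk_ids)
    bivalent = call_bivalent(k4_narrow, k27_narrow, sample_id, k4_min_rpkm, k27_min_rpkm, fixed_bivalent)
    calls = call_super_bivalent(
        bivalent, zvec, baseline, k27_10kb.sample(sample_id), k27_cutoff, sample_id
    )
    calls.thresholds_used.update(
        {"k4_min_rpkm": k4_min_rpkm, "k27_min_rpkm": k27_min_rpkm,
         "fixed_bivalent": fixed_bivalent is not None}
    )
    return calls, zvec


def summary_table(
    calls: BivalencyCallSet, zvec: ZScoredVector, k27_10kb_rpkm: pd.Series
) -> pd.DataFrame:
    """Per-gene table (k4_z, k27_rpkm, bivalent, super_bivalent) for export."""
    genes = list(zvec.z.index)
    return pd.DataFrame(
        {
            "k4_z": zvec.z,
            "k27_rpkm": k27_10kb_rpkm.reindex(genes),
            "bivalent": [int(g in calls.bivalent_genes) for g in genes],
            "super_bivalent": [int(g in calls.super_bivalent_genes) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )


@dataclass(frozen=True)
class OverlapStat:
    """Shared-membership statistic between two gene sets."""

    set_a_label: str
    set_b_label: str
    n_a: int
    n_b: int
    n_shared: int
    pct_of_a: int | None

    def __post_init__(self):
        if self.n_shared > min(self.n_a, self.n_b):
            raise ValueError("shared count exceeds a set size")


def overlap(set_a: Iterable[str], set_b: Iterable[str],
            label_a: str = "A", label_b: str = "B") -> OverlapStat:
    """How much of set A is also in set B, as a rounded percentage of |A|.

    With an empty A the percentage is undefined and reported as None.
    """
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    pct = round(100 * shared / len(a)) if a else None
    return OverlapStat(label_a, label_b, len(a), len(b), shared, pct)


def recovery_scores(called: Iterable[str], truth: Iterable[str]) -> tuple[float, float]:
    """(precision, recall) of a called gene set against a planted truth set."""
    called, truth = set(called), set(truth)
    tp = len(called & truth)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall
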