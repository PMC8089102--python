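"""Bin-level WGBS methylation, sample correlation, and hierarchical clustering.

Methylation per 10-kb bin is the coverage-weighted fraction
sum(meth_count)/sum(total_count) over the CpGs in the bin; bins below a
minimum summed coverage are treated as missing.  Samples are compared with
pairwise-complete Pearson correlation and clustered with uncentred
correlation, s(x, y) = sum(x*y) / sqrt(sum(x^2) * sum(y^2)), distance 1 - s,
under average linkage — the similarity/linkage combination of the classic
Cluster 3.0 tool.  Unlike Pearson, uncentred correlation does not subtract
means, so it distinguishes samples that differ by a constant offset but is
invariant to a common positive scale.

Histone-mark bin-RPKM matrices cluster through the same functions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .chip_quant import EnrichmentMatrix, Window
from .io_formats import CpGTable

log = logging.getLogger(__name__)


@dataclass
class MethylBinMatrix:
    """Bins-by-samples methylation fractions plus per-bin summed CpG coverage.

    ``fraction`` is NaN exactly where ``coverage`` is below ``min_coverage``.
    """

    bins: list[Window]
    fraction: pd.DataFrame
    coverage: pd.DataFrame
    min_coverage: int

    def __post_init__(self):
        f = self.fraction.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(f, initial=1.0) < 0 or np.nanmax(f, initial=0.0) > 1:
                raise ValueError("methylation fractions must lie in [0, 1]")
        low = self.coverage.to_numpy() < self.min_coverage
        if not (np.isnan(f) == low).all():
            raise ValueError("fraction must be missing exactly where coverage < min_coverage")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fraction.columns)


def _bin_of_positions(bins: Sequence[Window], chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Index of the containing bin for each position, -1 when uncovered.

    Bins must be sorted and non-overlapping within each chromosome (genome
    tilings from ``genome_bins`` are).
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    for i, b in enumerate(bins):
        starts.setdefault(b.chrom, []).append(b.start)  # type: ignore[union-attr]
        ends.setdefault(b.chrom, []).append(b.end)      # type: ignore[union-attr]
        offsets.setdefault(b.chrom, []).append(i)       # type: ignore[union-attr]
    for c in starts:
        s = np.asarray(starts[c])
        if not (np.diff(s) > 0).all():
            raise ValueError(f"bins not sorted on {c}")
        starts[c], ends[c], offsets[c] = s, np.asarray(ends[c]), np.asarray(offsets[c])
    out = np.full(len(pos), -1, dtype=np.int64)
    for c in set(chrom.tolist()):
        if c not in starts:
            continue
        sel = chrom == c
        idx = np.searchsorted(starts[c], pos[sel], side="right") - 1
        ok = (idx >= 0) & (pos[sel] < ends[c][np.clip(idx, 0, None)])
        result = np.where(ok, offsets[c][np.clip(idx, 0, None)], -1)
        out[sel] = result
    return out


def bin_methylation(
    cpgs_by_sample: Mapping[str, CpGTable] | CpGTable,
    bins: Sequence[Window],
    min_coverage: int = 3,
) -> MethylBinMatrix:
    """Coverage-weighted methylation fraction per bin per sample.

    A bin's fraction is sum(meth)/sum(total) over its CpGs; bins whose summed
    total coverage is below ``min_coverage`` (including empty bins) are
    missing (NaN).
    """
    if isinstance(cpgs_by_sample, CpGTable):
        cpgs_by_sample = {cpgs_by_sample.sample_id: cpgs_by_sample}
    nbins = len(bins)
    frac: dict[str, np.ndarray] = {}
    cov: dict[str, np.ndarray] = {}
    for sample_id, cpgs in cpgs_by_sample.items():
        idx = _bin_of_positions(bins, cpgs.chrom, cpgs.pos)
        inside = idx >= 0
        meth = np.bincount(idx[inside], weights=cpgs.meth_count[inside], minlength=nbins)
        total = np.bincount(idx[inside], weights=cpgs.total_count[inside], minlength=nbins)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(total >= min_coverage, meth / np.maximum(total, 1), np.nan)
        frac[sample_id] = f
        cov[sample_id] = total.astype(np.int64)
    index = [b.id for b in bins]
    return MethylBinMatrix(
        list(bins),
        pd.DataFrame(frac, index=index),
        pd.DataFrame(cov, index=index),
        min_coverage,
    )


class PearsonResult(NamedTuple):
    r: float
    n_bins: int


def pairwise_pearson(matrix: MethylBinMatrix | pd.DataFrame, sample_a: str, sample_b: str) -> PearsonResult:
    """Pearson r between two samples over bins non-missing in both."""
    df = matrix.fraction if isinstance(matrix, MethylBinMatrix) else matrix
    a, b = df[sample_a], df[sample_b]
    shared = a.notna() & b.notna()
    n = int(shared.sum())
    if n < 3:
        raise ValueError(f"only {n} bins shared between {sample_a} and {sample_b}; need >= 3")
    if sample_a == sample_b:
        return PearsonResult(1.0, n)
    r = float(pearsonr(a[shared], b[shared]).statistic)
    return PearsonResult(r, n)


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine-style similarity sum(xy)/sqrt(sum(x^2) sum(y^2)), no mean removal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        raise ValueError("uncentered correlation undefined for an all-zero vector")
    return float((x * y).sum() / denom)


@dataclass
class SampleTree:
    """Agglomerative sample dendrogram (leaves in lexicographic order).

    ``linkage_matrix`` is the scipy encoding; heights are 1 - similarity and
    are non-decreasing under average linkage.
    """

    leaves: tuple[str, ...]
    linkage_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster label per sample at k clusters."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.leaves, (int(v) for v in labels)))

    def clades(self, k: int) -> list[frozenset[str]]:
        assignment = self.cut(k)
        groups: dict[int, set[str]] = {}
        for leaf, c in assignment.items():
            groups.setdefault(c, set()).add(leaf)
        return sorted((frozenset(v) for v in groups.values()), key=lambda s: sorted(s)[0])

    def to_newick(self) -> str:
        node = hierarchy.to_tree(self.linkage_matrix)

        def walk(n) -> str:
            if n.is_leaf():
                return self.leaves[n.id]
            left, right = walk(n.left), walk(n.right)
            dl = n.dist - (0 if n.left.is_leaf() else n.left.dist)
            dr = n.dist - (0 if n.right.is_leaf() else n.right.dist)
            return f"({left}:{max(dl, 0):.6g},{right}:{max(dr, 0):.6g})"

        return walk(node) + ";"


def cluster_samples(
    matrix: MethylBinMatrix | EnrichmentMatrix | pd.DataFrame,
    similarity: str = "uncentered_correlation",
    linkage: str = "average",
) -> SampleTree:
    """Cluster samples over bins with 1 - similarity distance.

    Missing bins are handled pairwise-complete.  Samples are sorted by label
    before linkage so the tree is invariant to input column order, and ties
    are broken lexicographically.
    """
    if isinstance(matrix, MethylBinMatrix):
        df = matrix.fraction
    elif isinstance(matrix, EnrichmentMatrix):
        df = matrix.values
    else:
        df = matrix
    samples = sorted(df.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    for s in samples:
        if df[s].isna().all():
            raise ValueError(f"sample {s} has no non-missing bins")
    sim_fns = {
        "uncentered_correlation": uncentered_correlation,
        "pearson": lambda x, y: float(np.corrcoef(x, y)[0, 1]),
    }
    if similarity not in sim_fns:
        raise ValueError(f"unknown similarity {similarity!r}")
    fn = sim_fns[similarity]
    n = len(samples)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = df[samples[i]], df[samples[j]]
        shared = (a.notna() & b.notna()).to_numpy()
        if shared.sum() < 2:
            raise ValueError(f"samples {samples[i]} and {samples[j]} share < 2 bins")
        d = 1.0 - fn(a.to_numpy()[shared], b.to_numpy()[shared])
        dist[i, j] = dist[j, i] = d
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return SampleTree(tuple(samples), Z)
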