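"""ChIP-seq quantification: promoter/bin RPKM matrices and TSS meta-profiles.

A read is assigned to a window when its midpoint falls inside the window's
half-open span.  The midpoint rule makes genome tiling a partition of the
library (bin counts sum exactly to the number of mapped reads) and is the
standard choice for short, fragment-length intervals.  Enrichment is plain
RPKM — reads per kilobase of window per million mapped reads — with the
library size taken as all reads supplied (assumed deduplicated and uniquely
mapped); no input subtraction, spike-in scaling or pseudocounts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeDef, ReadIntervals, validate_genes

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """A half-open genomic window, optionally anchored to a gene."""

    chrom: str
    start: int
    end: int
    anchor_gene: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad window {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return self.anchor_gene or f"{self.chrom}:{self.start}-{self.end}"


def promoter_window(gene: GeneModel, genome: GenomeDef, window_bp: int = 10_000) -> Window:
    """TSS-centred window of ``window_bp``, clipped at chromosome ends.

    RPKM downstream uses the clipped length so boundary genes are not inflated.
    """
    if window_bp % 2 or window_bp <= 0:
        raise ValueError("window_bp must be a positive even number")
    half = window_bp // 2
    length = genome.length_of(gene.chrom)
    start = max(0, gene.tss - half)
    end = min(length, gene.tss + half)
    return Window(gene.chrom, start, end, anchor_gene=gene.gene_id)


class ReadIndex:
    """Sorted per-chromosome read midpoints for O(log n) window counting."""

    def __init__(self, reads: ReadIntervals, genome: GenomeDef | None = None):
        self.mark = reads.mark
        self.sample_id = reads.sample_id
        self.library_size = len(reads)
        self._mid: dict[str, np.ndarray] = {}
        mids = reads.midpoint
        if genome is not None and len(reads):
            for chrom in set(reads.chrom.tolist()):
                if chrom not in genome:
                    raise KeyError(f"reads on unknown chromosome {chrom!r}")
            lengths = np.fromiter(
                (genome.length_of(c) for c in reads.chrom), dtype=np.int64, count=len(reads)
            )
            if (reads.end > lengths).any():
                raise ValueError("read interval extends past chromosome end")
        if len(reads):
            order = np.argsort(reads.chrom.astype(str), kind="stable")
            chroms = reads.chrom[order]
            mids = mids[order]
            # split into per-chromosome sorted arrays
            boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
            for chunk_chrom, chunk in zip(
                chroms[np.concatenate([[0], boundaries])],
                np.split(mids, boundaries),
            ):
                self._mid[str(chunk_chrom)] = np.sort(chunk)
        self._known_chroms = set(genome.chrom_names) if genome is not None else None

    def count(self, window: Window) -> int:
        return int(self.count_many([window.chrom], [window.start], [window.end])[0])

    def count_many(self, chroms: Sequence[str], starts, ends) -> np.ndarray:
        """Midpoint counts for many windows; vectorised per chromosome."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=np.int64)
        chroms = np.asarray(chroms, dtype=object)
        for chrom in set(chroms.tolist()):
            if self._known_chroms is not None and chrom not in self._known_chroms:
                raise KeyError(f"window on unknown chromosome {chrom!r}")
            sel = chroms == chrom
            mid = self._mid.get(chrom)
            if mid is None:
                continue
            lo = np.searchsorted(mid, starts[sel], side="left")
            hi = np.searchsorted(mid, ends[sel], side="left")
            out[sel] = hi - lo
        return out

    def midpoints(self, chrom: str) -> np.ndarray:
        return self._mid.get(chrom, np.empty(0, dtype=np.int64))


def count_reads_in_window(reads: ReadIntervals | ReadIndex, window: Window,
                          genome: GenomeDef | None = None) -> int:
    """Number of reads whose midpoint lies in ``[start, end)``."""
    index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads, genome)
    if index._known_chroms is not None and window.chrom not in index._known_chroms:
        raise KeyError(f"window on unknown chromosome {window.chrom!r}")
    return index.count(window)


def rpkm(count, window_length_bp, library_size) -> float | np.ndarray:
    """Reads per kilobase of window per million mapped reads."""
    length = np.asarray(window_length_bp, dtype=float)
    if np.any(length <= 0):
        raise ValueError("window length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    value = np.asarray(count, dtype=float) / (length / 1e3) / (library_size / 1e6)
    return float(value) if np.isscalar(count) or np.ndim(count) == 0 else value


@dataclass
class EnrichmentMatrix:
    """Rows (genes or bins) by samples RPKM for one histone mark."""

    mark: str
    values: pd.DataFrame          # rows x samples, RPKM
    library_sizes: pd.Series      # per sample, total mapped reads
    windows: list[Window] = field(default_factory=list)

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("enrichment matrix rows/samples must be unique")
        arr = v.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("enrichment values must be finite and non-negative")
        if set(v.columns) != set(self.library_sizes.index):
            raise ValueError("library_sizes must cover exactly the sample columns")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


def _as_index(reads, genome: GenomeDef) -> ReadIndex:
    return reads if isinstance(reads, ReadIndex) else ReadIndex(reads, genome)


def promoter_enrichment_matrix(
    genes: Sequence[GeneModel],
    reads_by_sample: Mapping[str, ReadIntervals | ReadIndex],
    mark: str,
    genome: GenomeDef,
    window_bp: int = 10_000,
) -> EnrichmentMatrix:
    """Gene-by-sample RPKM over TSS-centred promoter windows."""
    validate_genes(genes, genome)
    windows = [promoter_window(g, genome, window_bp) for g in genes]
    chroms = [w.chrom for w in windows]
    starts = [w.start for w in windows]
    ends = [w.end for w in windows]
    lengths = np.array([w.length for w in windows], dtype=float)
    columns: dict[str, np.ndarray] = {}
    lib: dict[str, int] = {}
    for sample_id, reads in reads_by_sample.items():
        index = _as_index(reads, genome)
        if index.mark != mark:
            raise ValueError(f"sample {sample_id}: mark {index.mark} != requested {mark}")
        counts = index.count_many(chroms, starts, ends)
        lib[sample_id] = index.library_size
        columns[sample_id] = rpkm(counts, lengths, index.library_size) if index.library_size else np.zeros(len(genes))
    values = pd.DataFrame(columns, index=[w.id for w in windows])
    return EnrichmentMatrix(mark, values, pd.Series(lib), windows)


# ---------------------------------------------------------------------------
# meta-gene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Average strand-oriented coverage profile around the TSS of a gene set.

    Values are per-bin RPKM averaged over genes and divided by the mean 10-kb
    promoter RPKM of housekeeping genes, so 1.0 means "as strong as an average
    housekeeping promoter".
    """

    mark: str
    gene_set_label: str
    positions: np.ndarray   # bin-centre offsets from the TSS, bp
    values: np.ndarray      # normalised mean coverage
    bin_bp: int
    n_genes: int

    def half_max_width(self) -> float:
        """Width (bp) of the span where the profile is >= half its maximum."""
        if not len(self.values) or self.values.max() <= 0:
            return 0.0
        above = np.flatnonzero(self.values >= self.values.max() / 2)
        return float((above[-1] - above[0] + 1) * self.bin_bp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_bp": self.positions, self.gene_set_label: self.values})


def metagene_profile(
    genes_subset: Sequence[GeneModel],
    reads: ReadIntervals | ReadIndex,
    genome: GenomeDef,
    hk_mean_rpkm: float,
    label: str = "genes",
    window_bp: int = 10_000,
    bin_bp: int = 100,
) -> MetaProfile:
    """Housekeeping-normalised average TSS profile for a gene subset.

    Profiles of minus-strand genes are reversed before averaging so "right of
    the TSS" always means downstream.  Genes whose full window does not fit on
    the chromosome are dropped with a warning.
    """
    if not genes_subset:
        raise ValueError("empty gene subset")
    if window_bp % 2 or window_bp % bin_bp:
        raise ValueError("window_bp must be even and a multiple of bin_bp")
    if hk_mean_rpkm <= 0:
        raise ValueError("hk_mean_rpkm must be positive")
    index = _as_index(reads, genome)
    half = window_bp // 2
    nbins = window_bp // bin_bp
    total = np.zeros(nbins, dtype=float)
    used = 0
    for g in genes_subset:
        start, end = g.tss - half, g.tss + half
        if start < 0 or end > genome.length_of(g.chrom):
            log.warning("metagene: dropping %s (window clipped at chromosome end)", g.gene_id)
            continue
        mid = index.midpoints(g.chrom)
        lo, hi = np.searchsorted(mid, [start, end], side="left")
        binned = np.bincount((mid[lo:hi] - start) // bin_bp, minlength=nbins).astype(float)
        if g.strand == "-":
            binned = binned[::-1]
        total += binned
        used += 1
    if used == 0:
        raise ValueError("no gene in the subset has a full TSS window on its chromosome")
    mean_counts = total / used
    lib = index.library_size
    values = rpkm(mean_counts, float(bin_bp), lib) / hk_mean_rpkm if lib else mean_counts
    positions = np.arange(nbins) * bin_bp - half + bin_bp // 2
    return MetaProfile(index.mark, label, positions, np.asarray(values, dtype=float), bin_bp, used)


# ---------------------------------------------------------------------------
# genome bins
# ---------------------------------------------------------------------------

def genome_bins(genome: GenomeDef, bin_bp: int = 10_000) -> list[Window]:
    """Tile every chromosome with fixed-size bins; the last bin is truncated."""
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    bins: list[Window] = []
    for chrom, length in genome.items():
        for start in range(0, length, bin_bp):
            bins.append(Window(chrom, start, min(start + bin_bp, length)))
    return bins


def bin_enrichment_matrix(
    genome: GenomeDef,
    reads_by_sample: Mapping[str, ReadIntervals | ReadIndex],
    mark: str,
    bin_bp: int = 10_000,
) -> EnrichmentMatrix:
    """Bin-by-sample RPKM over a whole-genome tiling (for clustering)."""
    bins = genome_bins(genome, bin_bp)
    lengths = np.array([b.length for b in bins], dtype=float)
    nbins_per_chrom = {c: -(-length // bin_bp) for c, length in genome.items()}
    columns: dict[str, np.ndarray] = {}
    lib: dict[str, int] = {}
    for sample_id, reads in reads_by_sample.items():
        index = _as_index(reads, genome)
        if index.mark != mark:
            raise ValueError(f"sample {sample_id}: mark {index.mark} != requested {mark}")
        parts = []
        for chrom, _ in genome.items():
            mid = index.midpoints(chrom)
            parts.append(np.bincount(mid // bin_bp, minlength=nbins_per_chrom[chrom]).astype(np.int64))
        counts = np.concatenate(parts)
        lib[sample_id] = index.library_size
        columns[sample_id] = rpkm(counts, lengths, index.library_size) if index.library_size else np.zeros(len(bins))
    values = pd.DataFrame(columns, index=[b.id for b in bins])
    return EnrichmentMatrix(mark, values, pd.Series(lib), bins)


# ---------------------------------------------------------------------------
# bedGraph pileup path
# ---------------------------------------------------------------------------

def reads_to_midpoint_track(reads: ReadIntervals | ReadIndex, genome: GenomeDef) -> pd.DataFrame:
    """Run-length bedGraph of per-base midpoint counts.

    Window sums over this track reproduce midpoint window counts exactly, so a
    pre-piled track can substitute for raw reads without changing any RPKM.
    """
    index = _as_index(reads, genome)
    rows = []
    for chrom, _ in genome.items():
        mid = index.midpoints(chrom)
        if not len(mid):
            continue
        pos, counts = np.unique(mid, return_counts=True)
        for p, c in zip(pos, counts):
            rows.append((chrom, int(p), int(p) + 1, float(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def track_window_sum(track: pd.DataFrame, window: Window) -> float:
    """Sum of value x overlap length of a bedGraph track over a window."""
    sel = track[track["chrom"] == window.chrom]
    overlap = (
        np.minimum(sel["end"].to_numpy(), window.end)
        - np.maximum(sel["start"].to_numpy(), window.start)
    ).clip(min=0)
    return float((overlap * sel["value"].to_numpy()).sum())
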