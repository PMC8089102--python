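"""Readers and writers for the plain-text genomic formats the pipeline touches.

Every coordinate in memory and on disk is 0-based half-open (the BED
convention).  The single exception is GTF input, which is 1-based closed and
is converted on read; nothing downstream ever sees a 1-based coordinate.

Formats handled here: UCSC two-column ``chrom.sizes``, BED3 read intervals,
bedGraph tracks, gene models as TSV (or GTF-lite, gene features only),
plain-text gene lists, CpG methylation tables (chrom / pos / meth_count /
total_count TSV), and generic row-by-sample TSV matrices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27me3")
STRANDS = ("+", "-")
#: chromatin classes a synthetic gene may be planted with
GENE_CLASSES = ("housekeeping", "bivalent", "super_bivalent", "active", "silent")


class FormatError(ValueError):
    """A file violated its format contract (parse failure or bad invariant)."""


# ---------------------------------------------------------------------------
# genome definition
# ---------------------------------------------------------------------------

class GenomeDef:
    """Ordered chromosome names with lengths, i.e. a parsed chrom.sizes file.

    The chromosome order is fixed at construction and stable for the rest of
    the run; bins, matrices and bedGraph output all follow it.
    """

    def __init__(self, chrom_names: Sequence[str], chrom_lengths: Sequence[int]):
        names = [str(n) for n in chrom_names]
        lengths = [int(v) for v in chrom_lengths]
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if not names:
            raise FormatError("no chromosomes")
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names")
        bad = [n for n, v in zip(names, lengths) if v < 1]
        if bad:
            raise FormatError(f"non-positive length for chromosome(s): {bad}")
        self.chrom_names: tuple[str, ...] = tuple(names)
        self._lengths: dict[str, int] = dict(zip(names, lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self.chrom_names)

    def items(self) -> Iterable[tuple[str, int]]:
        for name in self.chrom_names:
            yield name, self._lengths[name]

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenomeDef({len(self)} chromosomes, {self.total_length} bp)"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeDef)
            and self.chrom_names == other.chrom_names
            and self._lengths == other._lengths
        )


def read_chrom_sizes(path) -> GenomeDef:
    """Parse a UCSC two-column chrom.sizes file (name, length)."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: length {fields[1]!r} is not an integer"
                ) from None
            if fields[0] in names:
                raise FormatError(f"{path}: line {lineno}: duplicate chromosome {fields[0]!r}")
            if length < 1:
                raise FormatError(f"{path}: line {lineno}: non-positive length {length}")
            names.append(fields[0])
            lengths.append(length)
    if not names:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeDef(names, lengths)


def write_chrom_sizes(genome: GenomeDef, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what promoter analysis needs: an anchored TSS.

    ``true_class`` carries the planted chromatin class on synthetic data only;
    real annotation leaves it ``None``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    is_housekeeping: bool = False
    true_class: str | None = None

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.tss < 0:
            raise FormatError(f"gene {self.gene_id}: negative TSS {self.tss}")
        if self.true_class is not None and self.true_class not in GENE_CLASSES:
            raise FormatError(f"gene {self.gene_id}: unknown class {self.true_class!r}")


def validate_genes(genes: Sequence[GeneModel], genome: GenomeDef) -> None:
    """Check every gene sits on a known chromosome with TSS inside it."""
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if not (0 <= g.tss < genome.length_of(g.chrom)):
            raise FormatError(
                f"gene {g.gene_id}: TSS {g.tss} outside {g.chrom} "
                f"(length {genome.length_of(g.chrom)})"
            )


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def _read_gtf_genes(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "gene":
                continue
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise FormatError(f"{path}: line {lineno}: gene feature without gene_id")
            start0 = int(start) - 1  # GTF is 1-based closed
            end0 = int(end)
            tss = start0 if strand == "+" else end0 - 1
            genes.append(GeneModel(m.group(1), chrom, strand, tss))
    return genes


def read_gene_models(path, housekeeping_list=None) -> list[GeneModel]:
    """Load gene models from a TSV (gene_id/chrom/strand/tss header) or a GTF.

    ``housekeeping_list`` may be a path to a one-ID-per-line file or an
    iterable of gene IDs; matching genes get the housekeeping flag in addition
    to any ``is_housekeeping`` column.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        genes = _read_gtf_genes(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
        required = {"gene_id", "chrom", "strand", "tss"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        genes = []
        for row in df.itertuples(index=False):
            hk = bool(int(getattr(row, "is_housekeeping", 0) or 0))
            cls = getattr(row, "true_class", None)
            if cls is not None and (pd.isna(cls) or cls == ""):
                cls = None
            genes.append(GeneModel(row.gene_id, row.chrom, row.strand, int(row.tss), hk, cls))
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    if housekeeping_list is not None:
        hk_ids = set(
            read_gene_list(housekeeping_list)
            if isinstance(housekeeping_list, (str, Path))
            else housekeeping_list
        )
        unknown = hk_ids - seen
        if unknown:
            raise FormatError(f"housekeeping IDs absent from gene models: {sorted(unknown)}")
        genes = [
            GeneModel(g.gene_id, g.chrom, g.strand, g.tss, g.is_housekeeping or g.gene_id in hk_ids, g.true_class)
            for g in genes
        ]
    log.info("read %d gene models from %s", len(genes), path)
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tis_housekeeping\ttrue_class\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{int(g.is_housekeeping)}\t{g.true_class or ''}\n"
            )


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines and #-comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


# ---------------------------------------------------------------------------
# read intervals
# ---------------------------------------------------------------------------

class ReadIntervals:
    """Aligned-read intervals for one histone mark in one sample.

    Held as parallel numpy arrays (chrom / start / end) so that windowed
    counting stays vectorised even at millions of reads.  Intervals are
    0-based half-open and validated at construction.
    """

    def __init__(self, chrom, start, end, mark: str, sample_id: str):
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValueError("chrom/start/end arrays differ in length")
        if mark not in MARKS:
            raise FormatError(f"unknown mark {mark!r}; expected one of {MARKS}")
        if len(self.start):
            if self.start.min() < 0:
                raise FormatError("negative interval start")
            if not (self.end > self.start).all():
                i = int(np.argmax(self.end <= self.start))
                raise FormatError(
                    f"interval end <= start at record {i}: "
                    f"{self.chrom[i]}:{self.start[i]}-{self.end[i]}"
                )
        self.mark = mark
        self.sample_id = sample_id

    def __len__(self) -> int:
        return len(self.start)

    @property
    def midpoint(self) -> np.ndarray:
        """Integer midpoints; the single point a read is assigned to a window by."""
        return (self.start + self.end) // 2

    @classmethod
    def empty(cls, mark: str, sample_id: str) -> "ReadIntervals":
        return cls([], [], [], mark, sample_id)

    @classmethod
    def concat(cls, parts: Sequence["ReadIntervals"]) -> "ReadIntervals":
        if not parts:
            raise ValueError("nothing to concatenate")
        marks = {p.mark for p in parts}
        samples = {p.sample_id for p in parts}
        if len(marks) > 1 or len(samples) > 1:
            raise ValueError("cannot concatenate across marks or samples")
        return cls(
            np.concatenate([p.chrom for p in parts]) if parts else [],
            np.concatenate([p.start for p in parts]),
            np.concatenate([p.end for p in parts]),
            parts[0].mark,
            parts[0].sample_id,
        )


def read_bed_reads(path, mark: str, sample_id: str) -> ReadIntervals:
    """Load a BED3+ file of deduplicated, uniquely-mapped read intervals."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        return ReadIntervals.empty(mark, sample_id)
    reads = ReadIntervals(df["chrom"].to_numpy(dtype=object), df["start"], df["end"], mark, sample_id)
    log.info("read %d %s intervals for sample %s from %s", len(reads), mark, sample_id, path)
    return reads


def write_bed_reads(reads: ReadIntervals, path) -> None:
    with open(path, "w") as fh:
        for c, s, e in zip(reads.chrom, reads.start, reads.end):
            fh.write(f"{c}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# CpG methylation tables
# ---------------------------------------------------------------------------

class CpGTable:
    """Per-CpG methylated / total read counts for one WGBS sample."""

    def __init__(self, chrom, pos, meth_count, total_count, sample_id: str = "sample"):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.meth_count = np.asarray(meth_count, dtype=np.int64)
        self.total_count = np.asarray(total_count, dtype=np.int64)
        n = len(self.chrom)
        if not (len(self.pos) == len(self.meth_count) == len(self.total_count) == n):
            raise ValueError("CpG arrays differ in length")
        if n:
            if self.pos.min() < 0:
                raise FormatError("negative CpG position")
            if self.total_count.min() < 1:
                raise FormatError("CpG total_count must be positive")
            if (self.meth_count < 0).any() or (self.meth_count > self.total_count).any():
                raise FormatError("CpG meth_count must satisfy 0 <= meth <= total")
        self.sample_id = sample_id

    def __len__(self) -> int:
        return len(self.pos)


def read_cpg_table(path, sample_id: str | None = None) -> CpGTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "meth_count", "total_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return CpGTable(
        df["chrom"].to_numpy(dtype=object), df["pos"], df["meth_count"], df["total_count"],
        sample_id or Path(path).stem,
    )


def write_cpg_table(cpgs: CpGTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tmeth_count\ttotal_count\n")
        for c, p, m, t in zip(cpgs.chrom, cpgs.pos, cpgs.meth_count, cpgs.total_count):
            fh.write(f"{c}\t{p}\t{m}\t{t}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track, path) -> None:
    """Write (chrom, start, end, value) records as bedGraph.

    Intervals must be sorted and non-overlapping within each chromosome;
    values survive a round-trip to at least 6 decimals.
    """
    rows = list(track.itertuples(index=False)) if isinstance(track, pd.DataFrame) else list(track)
    last: dict[str, int] = {}
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            start, end = int(start), int(end)
            if end <= start:
                raise FormatError(f"bedGraph interval end <= start: {chrom}:{start}-{end}")
            if start < last.get(chrom, 0) and chrom in last:
                raise FormatError(
                    f"bedGraph intervals overlap or are unsorted on {chrom} at {start}"
                )
            last[chrom] = end
            fh.write(f"{chrom}\t{start}\t{end}\t{float(value):.6f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith(("track", "browser"))].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path, float_format: str = "%.6g", index_label: str = "id") -> None:
    """Row-by-sample matrix as TSV with a stable float format (byte-reproducible)."""
    df.to_csv(path, sep="\t", float_format=float_format, index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
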