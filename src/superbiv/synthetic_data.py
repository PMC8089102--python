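"""Synthetic genomes, chromatin, methylomes and expression with planted truth.

The generator emulates the statistical regimes the downstream classification
assumes, on a scaled-down genome:

* genes on a regular grid, each planted into one of five chromatin classes —
  housekeeping, active, bivalent, super_bivalent, silent;
* H3K4me3 as a narrow TSS-centred domain (housekeeping / active / bivalent)
  or a broad one (super_bivalent), with the bivalent narrow domain weaker so
  bivalent promoter enrichment sits below the housekeeping average while
  super-bivalent enrichment sits above it;
* H3K27me3 as a broad domain at bivalent, super-bivalent and silent genes;
* a uniform genome-wide background at a low read rate;
* per-CpG binomial methylation with hypomethylated valleys over the
  promoters of developmental (bivalent + super-bivalent) genes;
* three-group FPKM matrices with planted group-specific genes.

Default depths give per-mark libraries of roughly a million reads on the
12-Mb default genome, so RPKM magnitudes (background well below 1, promoter
signal far above it) resemble real 10-20M-read libraries on a mammalian
genome.  Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CpGTable, GeneModel, GenomeDef, ReadIntervals
from .transcriptome import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_N_GENES: dict[str, int] = {
    "housekeeping": 50,
    "bivalent": 60,
    "super_bivalent": 30,
    "active": 40,
    "silent": 40,
}

DEFAULT_GROUPS: tuple[str, ...] = ("formative", "naive", "primed")

#: planted expression classes: one group-specific class per group, plus a
#: flat class; the high group clears both tripartite thresholds (FC 3, FPKM 9)
DEFAULT_EXPR_MEANS: dict[str, dict[str, float]] = {
    "formative_high": {"formative": 9.0, "naive": 3.0, "primed": 3.0},
    "naive_high": {"formative": 3.0, "naive": 9.0, "primed": 3.0},
    "primed_high": {"formative": 3.0, "naive": 3.0, "primed": 9.0},
    "flat": {"formative": 5.0, "naive": 5.0, "primed": 5.0},
}

DEVELOPMENTAL_CLASSES: tuple[str, ...] = ("bivalent", "super_bivalent")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset; defaults are the study conditions."""

    seed: int = 0
    n_genes_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_GENES))
    chrom_name: str = "chr1"
    chrom_length: int = 12_000_000
    gene_spacing: int = 50_000
    read_length: int = 50
    background_read_rate: float = 0.05      # reads/kb, genome-wide
    k4_narrow_width: int = 2_000            # bp, housekeeping/active/bivalent domains
    k4_broad_width: int = 8_000             # bp, super-bivalent domains
    k4_narrow_depth: float = 2_000.0        # reads/kb over housekeeping/active domains
    k4_broad_depth: float = 2_000.0         # reads/kb over super-bivalent domains
    k4_bivalent_depth: float = 800.0        # reads/kb over bivalent narrow domains
    k27_depth: float = 1_000.0              # reads/kb over H3K27me3 domains
    meth_global_level: float = 0.8
    meth_valley_level: float = 0.1
    cpg_spacing: int = 100                  # bp between simulated CpGs
    cpg_coverage: int = 20                  # WGBS reads per CpG
    expr_group_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EXPR_MEANS.items()}
    )
    expr_cv: float = 0.2

    def validate(self) -> None:
        if self.chrom_length < 1 or self.gene_spacing < 1:
            raise ValueError("chrom_length and gene_spacing must be positive")
        if max(self.k4_narrow_width, self.k4_broad_width) >= self.gene_spacing:
            raise ValueError("domain widths must be smaller than gene_spacing")
        for name in ("k4_narrow_depth", "k4_broad_depth", "k4_bivalent_depth",
                     "k27_depth", "background_read_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("meth_global_level", "meth_valley_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.expr_cv < 0:
            raise ValueError("expr_cv must be >= 0")
        unknown = set(self.n_genes_per_class) - {
            "housekeeping", "bivalent", "super_bivalent", "active", "silent"
        }
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")

    def rng(self, *tags: str) -> np.random.Generator:
        """Independent, reproducible stream named by string tags."""
        children = [zlib.crc32(t.encode()) for t in tags]
        return np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF, *children]))


class TruthTable:
    """Planted per-gene ground truth (chromatin class, hk flag, expression class)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"true_class", "is_housekeeping", "planted_expression_class"}
        if set(frame.columns) < required:
            raise ValueError(f"truth table needs columns {sorted(required)}")
        if frame.index.has_duplicates:
            raise ValueError("truth table gene_ids must be unique")
        self.frame = frame

    def genes_of_class(self, true_class: str) -> set[str]:
        return set(self.frame.index[self.frame["true_class"] == true_class])

    def genes_of_expression_class(self, cls: str) -> set[str]:
        return set(self.frame.index[self.frame["planted_expression_class"] == cls])

    @property
    def housekeeping_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["is_housekeeping"].astype(bool)])

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


def simulate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[GenomeDef, list[GeneModel], TruthTable]:
    """Place genes on a regular grid and assign planted classes.

    Genes sit at the centres of consecutive ``gene_spacing`` slots with
    alternating strands; chromatin classes are a seeded permutation of the
    per-class counts, and expression classes cycle through the configured
    class list so each chromatin class mixes all expression classes.
    """
    config.validate()
    n_total = sum(config.n_genes_per_class.values())
    if n_total * config.gene_spacing > config.chrom_length:
        raise ValueError(
            f"{n_total} genes at spacing {config.gene_spacing} do not fit on "
            f"{config.chrom_length} bp"
        )
    if config.gene_spacing < 10_000:
        warnings.warn(
            "gene_spacing below 10 kb: adjacent 10-kb promoter windows will overlap",
            stacklevel=2,
        )
    genome = GenomeDef([config.chrom_name], [config.chrom_length])
    classes = [c for c, n in sorted(config.n_genes_per_class.items()) for _ in range(n)]
    order = config.rng("gene_classes").permutation(len(classes))
    classes = [classes[i] for i in order]
    expr_classes = sorted(config.expr_group_means)
    genes: list[GeneModel] = []
    rows = {}
    for i, cls in enumerate(classes):
        gid = f"g{i:04d}"
        tss = config.gene_spacing // 2 + i * config.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        expr_cls = expr_classes[i % len(expr_classes)]
        genes.append(GeneModel(gid, config.chrom_name, strand, tss, cls == "housekeeping", cls))
        rows[gid] = {
            "true_class": cls,
            "is_housekeeping": cls == "housekeeping",
            "planted_expression_class": expr_cls,
        }
    truth = TruthTable(pd.DataFrame.from_dict(rows, orient="index"))
    return genome, genes, truth


def _k4_domain(cls: str, config: SimulationConfig) -> tuple[int, float] | None:
    """(width, depth) of a gene's H3K4me3 domain, None when unmarked."""
    if cls in ("housekeeping", "active"):
        return config.k4_narrow_width, config.k4_narrow_depth
    if cls == "bivalent":
        return config.k4_narrow_width, config.k4_bivalent_depth
    if cls == "super_bivalent":
        return config.k4_broad_width, config.k4_broad_depth
    return None


def _k27_domain(cls: str, config: SimulationConfig) -> tuple[int, float] | None:
    if cls in ("bivalent", "super_bivalent", "silent"):
        return config.k4_broad_width, config.k27_depth
    return None


def simulate_chip_reads(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    mark: str,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> ReadIntervals:
    """Poisson read counts placed uniformly over per-class TSS-centred domains.

    Per marked gene the read count is Poisson(depth * domain_kb); background
    reads fall uniformly genome-wide at ``background_read_rate`` per kb.
    """
    if mark not in ("H3K4me3", "H3K27me3"):
        raise ValueError(f"unknown mark {mark!r}")
    config.validate()
    if rng is None:
        rng = config.rng("chip", mark, sample_id)
    domain_of = _k4_domain if mark == "H3K4me3" else _k27_domain
    length = config.chrom_length
    max_start = length - config.read_length
    starts: list[np.ndarray] = []
    for g in genes:
        cls = truth.frame.loc[g.gene_id, "true_class"]
        domain = domain_of(cls, config)
        if domain is None:
            continue
        width, depth = domain
        n = rng.poisson(depth * width / 1e3)
        if n == 0:
            continue
        lo = max(0, g.tss - width // 2)
        hi = min(max_start, g.tss + width // 2 - config.read_length)
        starts.append(rng.integers(lo, max(hi, lo + 1), size=n))
    n_bg = rng.poisson(config.background_read_rate * length / 1e3)
    if n_bg:
        starts.append(rng.integers(0, max_start + 1, size=n_bg))
    if starts:
        start = np.concatenate(starts)
    else:
        start = np.empty(0, dtype=np.int64)
    return ReadIntervals(
        np.full(len(start), config.chrom_name, dtype=object),
        start,
        start + config.read_length,
        mark,
        sample_id,
    )


def simulate_methylome(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    valley_classes: Sequence[str] = DEVELOPMENTAL_CLASSES,
    valley_bp: int = 10_000,
    global_level: float | None = None,
) -> CpGTable:
    """CpGs on a regular grid with binomial counts; valleys at chosen classes.

    The methylation probability is ``meth_global_level`` (or ``global_level``
    when given, e.g. for a hypomethylated naive-like sample) everywhere except
    TSS-centred ``valley_bp`` windows of genes in ``valley_classes``, where it
    drops to ``meth_valley_level``.
    """
    config.validate()
    if rng is None:
        rng = config.rng("meth", sample_id)
    level = config.meth_global_level if global_level is None else float(global_level)
    pos = np.arange(0, config.chrom_length, config.cpg_spacing, dtype=np.int64)
    p = np.full(len(pos), level)
    valley_genes = set().union(*(truth.genes_of_class(c) for c in valley_classes)) if valley_classes else set()
    half = valley_bp // 2
    for g in genes:
        if g.gene_id not in valley_genes:
            continue
        lo, hi = np.searchsorted(pos, [max(0, g.tss - half), g.tss + half])
        p[lo:hi] = config.meth_valley_level
    meth = rng.binomial(config.cpg_coverage, p)
    return CpGTable(
        np.full(len(pos), config.chrom_name, dtype=object),
        pos,
        meth,
        np.full(len(pos), config.cpg_coverage, dtype=np.int64),
        sample_id,
    )


def simulate_expression(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    groups: Sequence[str] = DEFAULT_GROUPS,
    n_reps: int = 2,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Log-normal FPKM around the planted class/group means with CV expr_cv.

    CV 0 degenerates to the exact mean table.  The log-normal is
    mean-parameterised: sigma^2 = ln(1 + CV^2), mu = ln(mean) - sigma^2/2.
    """
    config.validate()
    if rng is None:
        rng = config.rng("expr")
    for cls, means in config.expr_group_means.items():
        missing = [g for g in groups if g not in means]
        if missing:
            raise ValueError(f"expr_group_means[{cls!r}] lacks groups {missing}")
    gene_ids = [g.gene_id for g in genes]
    mean_matrix = np.array(
        [
            [config.expr_group_means[truth.frame.loc[gid, "planted_expression_class"]][grp]
             for grp in groups for _ in range(n_reps)]
            for gid in gene_ids
        ]
    )
    samples = [f"{grp}_rep{r + 1}" for grp in groups for r in range(n_reps)]
    cv = config.expr_cv
    if cv == 0:
        values = mean_matrix
    else:
        sigma2 = np.log1p(cv * cv)
        with np.errstate(divide="ignore"):
            mu = np.where(mean_matrix > 0, np.log(np.maximum(mean_matrix, 1e-300)) - sigma2 / 2, -np.inf)
        noise = rng.normal(0.0, np.sqrt(sigma2), size=mean_matrix.shape)
        values = np.where(mean_matrix > 0, np.exp(mu + noise), 0.0)
    fpkm = pd.DataFrame(values, index=gene_ids, columns=samples)
    group_of_sample = {f"{grp}_rep{r + 1}": grp for grp in groups for r in range(n_reps)}
    return ExpressionMatrix(fpkm, group_of_sample)
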