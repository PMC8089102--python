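"""Reproducible orchestration: simulate -> quantify -> classify -> compare.

A run is described by a :class:`RunConfig` (usually a YAML file inside a
dataset directory).  ``run_pipeline`` executes the stages whose inputs are
configured, writes plain-text TSV outputs plus a machine-readable manifest
(parameters, input checksums, seed, package version, collected warnings),
and aborts with the failing stage's name on any error.  Given the same seed
and inputs, every numeric output is byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .bivalency import classify_sample, overlap, recovery_scores, summary_table
from .chip_quant import (
    EnrichmentMatrix,
    bin_enrichment_matrix,
    genome_bins,
    metagene_profile,
    promoter_enrichment_matrix,
)
from .io_formats import (
    MARKS,
    GeneModel,
    GenomeDef,
    read_bed_reads,
    read_chrom_sizes,
    read_cpg_table,
    read_gene_models,
    write_bed_reads,
    write_chrom_sizes,
    write_cpg_table,
    write_gene_list,
    write_gene_models,
    write_matrix_tsv,
)
from .methylome import bin_methylation, cluster_samples, pairwise_pearson
from .synthetic_data import (
    DEFAULT_GROUPS,
    DEVELOPMENTAL_CLASSES,
    SimulationConfig,
    TruthTable,
    simulate_chip_reads,
    simulate_expression,
    simulate_genome_and_genes,
    simulate_methylome,
)
from .transcriptome import (
    ExpressionMatrix,
    cluster_expression,
    deg_table,
    tripartite_deg,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Paths and parameters of one analysis run."""

    output_dir: str
    genome: str
    genes: str
    housekeeping: str | None = None
    chip_reads: dict[str, dict[str, str]] = field(default_factory=dict)  # sample -> mark -> path
    cpg_tables: dict[str, str] = field(default_factory=dict)             # sample -> path
    expression: str | None = None
    expression_groups: dict[str, str] | str | None = None                # sample -> group, or YAML path
    truth: str | None = None
    promoter_bp: int = 10_000
    heatmap_bp: int = 5_000      # the +/- 2.5 kb window of the bivalency thresholds
    bin_bp: int = 10_000
    k4_min_rpkm: float = 1.0
    k27_min_rpkm: float = 1.0
    k27_cutoff: float = 1.0
    fc_min: float = 1.5
    fpkm_min: float = 3.0
    min_coverage: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("promoter_bp", "heatmap_bp", "bin_bp", "k27_cutoff",
                     "fc_min", "fpkm_min", "min_coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        required: list[tuple[str, str | None]] = [("genome", self.genome), ("genes", self.genes)]
        if self.chip_reads:
            required.append(("housekeeping", self.housekeeping))
            for sample, marks in self.chip_reads.items():
                for mark, path in marks.items():
                    required.append((f"chip_reads[{sample}][{mark}]", path))
        for sample, path in self.cpg_tables.items():
            required.append((f"cpg_tables[{sample}]", path))
        if self.expression:
            required.append(("expression", self.expression))
            if self.expression_groups is None:
                raise PipelineError("config field 'expression_groups' is required with 'expression'")
            if isinstance(self.expression_groups, str):
                required.append(("expression_groups", self.expression_groups))
        if self.truth:
            required.append(("truth", self.truth))
        for name, path in required:
            if path is None:
                raise PipelineError(f"config field '{name}' is required but missing")
            if not Path(path).exists():
                raise PipelineError(f"config field '{name}': path {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        for key in ("genome", "genes", "housekeeping", "expression", "truth"):
            if data.get(key):
                data[key] = resolve(data[key])
        if isinstance(data.get("expression_groups"), str):
            data["expression_groups"] = resolve(data["expression_groups"])
        for sample, marks in data.get("chip_reads", {}).items():
            for mark in marks:
                marks[mark] = resolve(marks[mark])
        for sample in data.get("cpg_tables", {}):
            data["cpg_tables"][sample] = resolve(data["cpg_tables"][sample])
        data.setdefault("output_dir", str(base / "results"))
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
    outdir,
    chip_samples: tuple[str, ...] = ("fpsc", "e65epi"),
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    n_reps: int = 2,
) -> Path:
    """Generate a complete dataset directory plus its ``run.yaml``.

    ChIP samples are independent draws over the same planted truth (so their
    call sets should largely agree, like biological replicates of one state).
    The methylome gets four samples: two primed-like with developmental
    valleys (one per ChIP sample name) and two naive-like globally
    hypomethylated replicates, giving the clustering a planted pair structure.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    (outdir / "methylome").mkdir(exist_ok=True)
    genome, genes, truth = simulate_genome_and_genes(config)
    write_chrom_sizes(genome, outdir / "chrom.sizes")
    write_gene_models(genes, outdir / "genes.tsv")
    write_gene_list(truth.housekeeping_ids, outdir / "housekeeping.txt")
    truth.to_tsv(outdir / "truth.tsv")
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config.__dict__, fh, sort_keys=True)

    chip_reads: dict[str, dict[str, str]] = {}
    for sample in chip_samples:
        chip_reads[sample] = {}
        for mark in MARKS:
            reads = simulate_chip_reads(genes, truth, config, mark, sample_id=sample)
            path = outdir / "reads" / f"{sample}.{mark}.bed"
            write_bed_reads(reads, path)
            chip_reads[sample][mark] = str(path.relative_to(outdir))

    cpg_tables: dict[str, str] = {}
    meth_plan = {s: {} for s in chip_samples}
    meth_plan.update({"naive_r1": {"global_level": 0.3}, "naive_r2": {"global_level": 0.3}})
    for sample, kw in meth_plan.items():
        cpgs = simulate_methylome(genes, truth, config, sample_id=sample, **kw)
        path = outdir / "methylome" / f"{sample}.cpg.tsv"
        write_cpg_table(cpgs, path)
        cpg_tables[sample] = str(path.relative_to(outdir))

    expr = simulate_expression(genes, truth, config, groups=groups, n_reps=n_reps)
    write_matrix_tsv(expr.fpkm, outdir / "expression.tsv", index_label="gene_id")
    with open(outdir / "expression_groups.yaml", "w") as fh:
        yaml.safe_dump(expr.group_of_sample, fh, sort_keys=True)

    run = RunConfig(
        output_dir="results",
        genome="chrom.sizes",
        genes="genes.tsv",
        housekeeping="housekeeping.txt",
        chip_reads=chip_reads,
        cpg_tables=cpg_tables,
        expression="expression.tsv",
        expression_groups="expression_groups.yaml",
        truth="truth.tsv",
        seed=config.seed,
    )
    run.to_yaml(outdir / "run.yaml")
    return outdir


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

@dataclass
class _Context:
    genome: GenomeDef
    genes: list[GeneModel]
    hk_ids: list[str]
    truth: TruthTable | None


def _load_context(cfg: RunConfig) -> _Context:
    genome = read_chrom_sizes(cfg.genome)
    genes = read_gene_models(cfg.genes, housekeeping_list=cfg.housekeeping)
    hk_ids = [g.gene_id for g in genes if g.is_housekeeping]
    truth = TruthTable.from_tsv(cfg.truth) if cfg.truth else None
    return _Context(genome, genes, hk_ids, truth)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name}: {exc}") from exc
            log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("quantify")
def stage_quantify(cfg: RunConfig, ctx: _Context, outdir: Path) -> dict[str, EnrichmentMatrix]:
    """Promoter (10-kb and heatmap-width) and genome-bin RPKM matrices."""
    reads = {
        mark: {
            sample: read_bed_reads(paths[mark], mark, sample)
            for sample, paths in cfg.chip_reads.items()
        }
        for mark in MARKS
    }
    out: dict[str, EnrichmentMatrix] = {}
    for mark in MARKS:
        tag = mark.lower()
        out[f"{tag}_promoter"] = promoter_enrichment_matrix(
            ctx.genes, reads[mark], mark, ctx.genome, cfg.promoter_bp
        )
        out[f"{tag}_narrow"] = promoter_enrichment_matrix(
            ctx.genes, reads[mark], mark, ctx.genome, cfg.heatmap_bp
        )
        out[f"{tag}_bins"] = bin_enrichment_matrix(ctx.genome, reads[mark], mark, cfg.bin_bp)
        write_matrix_tsv(out[f"{tag}_promoter"].values, outdir / f"{tag}_promoter{cfg.promoter_bp}.tsv",
                         index_label="gene_id")
        write_matrix_tsv(out[f"{tag}_narrow"].values, outdir / f"{tag}_promoter{cfg.heatmap_bp}.tsv",
                         index_label="gene_id")
        write_matrix_tsv(out[f"{tag}_bins"].values, outdir / f"{tag}_bins{cfg.bin_bp}.tsv",
                         index_label="bin")
        if len(cfg.chip_reads) >= 2:
            tree = cluster_samples(out[f"{tag}_bins"])
            (outdir / f"{tag}_tree.newick").write_text(tree.to_newick() + "\n")
    out["_reads"] = reads  # type: ignore[assignment]
    return out


@_stage("call-bivalency")
def stage_bivalency(cfg: RunConfig, ctx: _Context, outdir: Path, matrices) -> dict:
    """Per-sample bivalency calls, meta-profiles, overlaps, recovery report."""
    if not ctx.hk_ids:
        raise ValueError("no housekeeping genes configured (field 'housekeeping')")
    k4p, k27p = matrices["h3k4me3_promoter"], matrices["h3k27me3_promoter"]
    k4n, k27n = matrices["h3k4me3_narrow"], matrices["h3k27me3_narrow"]
    reads = matrices["_reads"]
    genes_by_id = {g.gene_id: g for g in ctx.genes}
    calls = {}
    recovery_rows = []
    for sample in cfg.chip_reads:
        callset, zvec = classify_sample(
            sample, k4p, k27p, k4n, k27n, ctx.hk_ids,
            cfg.k4_min_rpkm, cfg.k27_min_rpkm, cfg.k27_cutoff,
        )
        calls[sample] = callset
        write_gene_list(sorted(callset.bivalent_genes), outdir / f"{sample}.bivalent.txt")
        write_gene_list(sorted(callset.super_bivalent_genes), outdir / f"{sample}.super_bivalent.txt")
        write_matrix_tsv(summary_table(callset, zvec, k27p.sample(sample)),
                         outdir / f"{sample}.bivalency.tsv", index_label="gene_id")

        hk_mean = float(k4p.sample(sample).loc[ctx.hk_ids].mean())
        subsets = {
            "housekeeping": [genes_by_id[g] for g in ctx.hk_ids],
            "bivalent": [genes_by_id[g] for g in sorted(callset.bivalent_genes - callset.super_bivalent_genes)],
            "super_bivalent": [genes_by_id[g] for g in sorted(callset.super_bivalent_genes)],
        }
        frames = []
        for label, subset in subsets.items():
            if not subset:
                continue
            prof = metagene_profile(
                subset, reads["H3K4me3"][sample], ctx.genome, hk_mean,
                label=label, window_bp=cfg.promoter_bp,
            )
            frames.append(prof.to_frame().set_index("offset_bp"))
        if frames:
            write_matrix_tsv(pd.concat(frames, axis=1), outdir / f"{sample}.k4_profiles.tsv",
                             index_label="offset_bp")
        if ctx.truth is not None:
            planted_biv = ctx.truth.genes_of_class("bivalent") | ctx.truth.genes_of_class("super_bivalent")
            bp, br = recovery_scores(callset.bivalent_genes, planted_biv)
            sp, sr = recovery_scores(callset.super_bivalent_genes,
                                     ctx.truth.genes_of_class("super_bivalent"))
            recovery_rows.append(
                {"sample": sample, "bivalent_precision": bp, "bivalent_recall": br,
                 "super_precision": sp, "super_recall": sr}
            )
    samples = list(cfg.chip_reads)
    overlap_rows = []
    for a in samples:
        for b in samples:
            if a == b:
                continue
            st = overlap(calls[a].super_bivalent_genes, calls[b].super_bivalent_genes, a, b)
            overlap_rows.append(
                {"set_a": a, "set_b": b, "n_a": st.n_a, "n_b": st.n_b,
                 "n_shared": st.n_shared, "pct_of_a": st.pct_of_a}
            )
    if overlap_rows:
        pd.DataFrame(overlap_rows).to_csv(outdir / "overlap_stats.tsv", sep="\t", index=False)
    if recovery_rows:
        pd.DataFrame(recovery_rows).to_csv(
            outdir / "recovery.tsv", sep="\t", index=False, float_format="%.6g"
        )
    return {"calls": calls, "recovery": recovery_rows, "overlaps": overlap_rows}


@_stage("methylome")
def stage_methylome(cfg: RunConfig, ctx: _Context, outdir: Path) -> dict:
    """Bin methylation matrix, pairwise Pearson table, sample dendrogram."""
    cpgs = {s: read_cpg_table(p, sample_id=s) for s, p in cfg.cpg_tables.items()}
    bins = genome_bins(ctx.genome, cfg.bin_bp)
    mat = bin_methylation(cpgs, bins, min_coverage=cfg.min_coverage)
    write_matrix_tsv(mat.fraction, outdir / "meth_bins.tsv", index_label="bin")
    write_matrix_tsv(mat.coverage, outdir / "meth_coverage.tsv", index_label="bin")
    samples = mat.sample_ids
    rows = []
    for a in samples:
        for b in samples:
            r, n = pairwise_pearson(mat, a, b)
            rows.append({"sample_a": a, "sample_b": b, "pearson_r": r, "n_bins": n})
    pd.DataFrame(rows).to_csv(outdir / "meth_pearson.tsv", sep="\t", index=False, float_format="%.6g")
    result = {"matrix": mat, "pearson": rows}
    if len(samples) >= 2:
        tree = cluster_samples(mat)
        (outdir / "meth_tree.newick").write_text(tree.to_newick() + "\n")
        result["tree"] = tree
    return result


@_stage("deg")
def stage_deg(cfg: RunConfig, ctx: _Context, outdir: Path) -> dict:
    """Tripartite DEG calls, per-group counts, and expression dendrogram."""
    fpkm = pd.read_csv(cfg.expression, sep="\t", index_col=0)
    groups_cfg = cfg.expression_groups
    if isinstance(groups_cfg, str):
        with open(groups_cfg) as fh:
            groups_cfg = yaml.safe_load(fh)
    matrix = ExpressionMatrix(fpkm, dict(groups_cfg))
    calls = tripartite_deg(matrix, fc_min=cfg.fc_min, fpkm_min=cfg.fpkm_min)
    table = deg_table(calls)
    write_matrix_tsv(table, outdir / "deg_calls.tsv", index_label="gene_id")
    counts = table["assigned_group"].value_counts().sort_index()
    counts.rename_axis("group").to_frame("n_genes").to_csv(outdir / "deg_counts.tsv", sep="\t")
    tree = cluster_expression(matrix)
    (outdir / "expr_tree.newick").write_text(tree.to_newick() + "\n")
    return {"matrix": matrix, "calls": calls, "counts": counts.to_dict()}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every configured stage and write the run manifest."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []
    results: dict = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ctx = _load_context(cfg)
        if cfg.chip_reads:
            matrices = stage_quantify(cfg, ctx, outdir)
            results["bivalency"] = stage_bivalency(cfg, ctx, outdir, matrices)
        if cfg.cpg_tables:
            results["methylome"] = stage_methylome(cfg, ctx, outdir)
        if cfg.expression:
            results["deg"] = stage_deg(cfg, ctx, outdir)
        collected = [str(w.message) for w in caught]

    checksums = {}
    for name, path in _input_paths(cfg):
        checksums[name] = _sha256(path)
    manifest = {
        "package": "superbiv",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: getattr(cfg, k)
            for k in ("promoter_bp", "heatmap_bp", "bin_bp", "k4_min_rpkm", "k27_min_rpkm",
                      "k27_cutoff", "fc_min", "fpkm_min", "min_coverage")
        },
        "input_checksums": checksums,
        "warnings": collected,
    }
    if results.get("bivalency", {}).get("recovery"):
        manifest["recovery"] = [
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
            for row in results["bivalency"]["recovery"]
        ]
    if "deg" in results:
        manifest["deg_counts"] = {str(k): int(v) for k, v in results["deg"]["counts"].items()}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# planted-truth evaluation (validation of the whole calling chain)
# ---------------------------------------------------------------------------

def evaluate_planted_recovery(
    config: SimulationConfig | None = None,
    n_replicates: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Precision/recall of bivalent and super-bivalent calls vs planted truth.

    Each replicate re-simulates reads for both marks under a distinct seed,
    quantifies promoter enrichment, classifies, and scores against the truth
    table.  Returns one row per replicate.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(**{**(config.__dict__ if config else {}),
                                  "seed": (base_seed + rep) & 0x7FFFFFFF})
        genome, genes, truth = simulate_genome_and_genes(cfg)
        reads = {
            mark: simulate_chip_reads(genes, truth, cfg, mark, sample_id="rep")
            for mark in MARKS
        }
        mats = {
            (mark, bp): promoter_enrichment_matrix(genes, {"rep": reads[mark]}, mark, genome, bp)
            for mark in MARKS for bp in (10_000, 5_000)
        }
        calls, _ = classify_sample(
            "rep", mats[("H3K4me3", 10_000)], mats[("H3K27me3", 10_000)],
            mats[("H3K4me3", 5_000)], mats[("H3K27me3", 5_000)],
            truth.housekeeping_ids,
        )
        planted_biv = truth.genes_of_class("bivalent") | truth.genes_of_class("super_bivalent")
        bp_, br = recovery_scores(calls.bivalent_genes, planted_biv)
        sp, sr = recovery_scores(calls.super_bivalent_genes,
                                 truth.genes_of_class("super_bivalent"))
        rows.append({"replicate": rep, "bivalent_precision": bp_, "bivalent_recall": br,
                     "super_precision": sp, "super_recall": sr})
    return pd.DataFrame(rows)


def evaluate_methylome_pairing(
    config: SimulationConfig | None = None,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> float:
    """Fraction of seeds where samples sharing valley placement pair up.

    Per seed, four methylomes are simulated: two with hypomethylated valleys
    at developmental (bivalent + super-bivalent) promoters and two with
    valleys shifted to active/silent promoters; success means the 2-clade cut
    of the uncentred-correlation average-linkage tree equals that pairing.
    """
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(**{**(config.__dict__ if config else {}),
                                  "seed": (base_seed + i) & 0x7FFFFFFF})
        genome, genes, truth = simulate_genome_and_genes(cfg)
        bins = genome_bins(genome, cfg.__dict__.get("bin_bp", 10_000))
        tables = {
            sample: simulate_methylome(genes, truth, cfg, sample_id=sample,
                                       valley_classes=classes)
            for sample, classes in (
                ("dev_a", DEVELOPMENTAL_CLASSES), ("dev_b", DEVELOPMENTAL_CLASSES),
                ("alt_a", ("active", "silent")), ("alt_b", ("active", "silent")),
            )
        }
        tree = cluster_samples(bin_methylation(tables, bins))
        if set(tree.clades(2)) == {frozenset({"dev_a", "dev_b"}),
                                   frozenset({"alt_a", "alt_b"})}:
            hits += 1
    return hits / n_seeds


def _input_paths(cfg: RunConfig):
    yield "genome", cfg.genome
    yield "genes", cfg.genes
    if cfg.housekeeping:
        yield "housekeeping", cfg.housekeeping
    for sample, marks in cfg.chip_reads.items():
        for mark, path in marks.items():
            yield f"chip:{sample}:{mark}", path
    for sample, path in cfg.cpg_tables.items():
        yield f"cpg:{sample}", path
    if cfg.expression:
        yield "expression", cfg.expression
    if isinstance(cfg.expression_groups, str):
        yield "expression_groups", cfg.expression_groups
    if cfg.truth:
        yield "truth", cfg.truth
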