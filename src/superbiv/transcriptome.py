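"""FPKM expression handling: the tripartite one-vs-rest DEG filter, marker
panels, qPCR 2^-dCt conversion, and sample clustering.

The tripartite classifier compares three cell-state groups (e.g. a formative,
a naive and a primed state): a gene is assigned to a group when its mean FPKM
there is at least ``fc_min`` (default 1.5) times the mean of *each* of the
other two groups and itself at least ``fpkm_min`` (default 3.0).  With a fold
change above 1 at most one group can win, so the rule partitions genes into
the three group-specific sets plus "none".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome import SampleTree, cluster_samples

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes-by-samples FPKM with a sample-to-group assignment."""

    fpkm: pd.DataFrame
    group_of_sample: dict[str, str]

    def __post_init__(self):
        if self.fpkm.index.has_duplicates or self.fpkm.columns.has_duplicates:
            raise ValueError("expression matrix genes/samples must be unique")
        missing = [s for s in self.fpkm.columns if s not in self.group_of_sample]
        if missing:
            raise ValueError(f"samples without a group: {missing}")
        arr = self.fpkm.to_numpy(dtype=float)
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("FPKM values must be finite and non-negative")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.fpkm.columns:
            g = self.group_of_sample[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s in self.fpkm.columns if self.group_of_sample[s] == group]

    def group_means(self) -> pd.DataFrame:
        """Arithmetic mean FPKM per gene per group (over replicate samples)."""
        cols = {}
        for g in self.groups:
            samples = self.samples_of_group(g)
            if not samples:
                raise ValueError(f"group {g} has no samples")
            cols[g] = self.fpkm[samples].mean(axis=1)
        return pd.DataFrame(cols)


def fpkm_from_counts(counts, gene_length_bp, library_size) -> float | np.ndarray:
    """Fragments per kilobase of gene per million mapped fragments."""
    if np.any(np.asarray(gene_length_bp) <= 0):
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    value = np.asarray(counts, dtype=float) / (np.asarray(gene_length_bp) / 1e3) / (library_size / 1e6)
    return float(value) if np.ndim(counts) == 0 else value


@dataclass(frozen=True)
class DEGCall:
    """One gene's tripartite classification result."""

    gene_id: str
    assigned_group: str          # one of the three groups, or "none"
    group_means: Mapping[str, float]
    fold_changes: Mapping[str, float]  # own-group mean / other-group mean


def tripartite_deg(
    matrix: ExpressionMatrix,
    groups: Sequence[str] | None = None,
    fc_min: float = 1.5,
    fpkm_min: float = 3.0,
) -> list[DEGCall]:
    """One-vs-two-others DEG assignment over exactly three groups.

    A gene belongs to group g iff mean_g >= fc_min * mean_h for both other
    groups h and mean_g >= fpkm_min.  A fold change against a zero mean is
    +inf, so such genes pass the fold-change arm whenever they are expressed
    at all.
    """
    groups = list(groups) if groups is not None else matrix.groups
    if len(groups) != 3:
        raise ValueError(f"tripartite classification needs exactly 3 groups, got {groups}")
    means = matrix.group_means()[groups]
    m = means.to_numpy(dtype=float)
    calls: list[DEGCall] = []
    for i, gene in enumerate(means.index):
        row = [float(v) for v in m[i]]
        assigned = "none"
        fold_changes: dict[str, float] = {}
        for gi, g in enumerate(groups):
            others = [o for o in range(3) if o != gi]
            fcs = [row[gi] / row[o] if row[o] > 0 else (math.inf if row[gi] > 0 else math.nan)
                   for o in others]
            ok = row[gi] >= fpkm_min and all(not math.isnan(f) and f >= fc_min for f in fcs)
            if ok:
                assigned = g
                fold_changes = {groups[o]: fcs[k] for k, o in enumerate(others)}
                break  # fc_min > 1 makes a second winner impossible
        calls.append(
            DEGCall(str(gene), assigned, dict(zip(groups, (float(v) for v in row))), fold_changes)
        )
    return calls


def deg_table(calls: Sequence[DEGCall]) -> pd.DataFrame:
    """Flatten DEG calls for TSV export."""
    if not calls:
        return pd.DataFrame(columns=["assigned_group"])
    groups = list(calls[0].group_means)
    rows = {
        c.gene_id: {
            "assigned_group": c.assigned_group,
            **{f"mean_{g}": c.group_means[g] for g in groups},
        }
        for c in calls
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")


@dataclass
class MarkerSummary:
    """Marker-panel means per group, with genes absent from the matrix listed."""

    per_gene: pd.DataFrame     # panel, gene_id, one column per group
    panel_means: pd.DataFrame  # panel x group mean FPKM
    missing: dict[str, list[str]] = field(default_factory=dict)


def marker_summary(matrix: ExpressionMatrix, panels: Mapping[str, Sequence[str]]) -> MarkerSummary:
    """Summarise named marker panels (e.g. formative / naive / primed sets).

    Genes absent from the matrix are reported under ``missing``, never
    silently dropped.
    """
    means = matrix.group_means()
    rows = []
    missing: dict[str, list[str]] = {}
    for panel, genes in panels.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"panel {panel!r} is empty")
        absent = [g for g in genes if g not in means.index]
        if absent:
            missing[panel] = absent
        for g in genes:
            if g in means.index:
                rows.append({"panel": panel, "gene_id": g, **means.loc[g].to_dict()})
    per_gene = pd.DataFrame(rows)
    if len(per_gene):
        panel_means = per_gene.groupby("panel")[list(means.columns)].mean()
    else:
        panel_means = pd.DataFrame(columns=list(means.columns))
    return MarkerSummary(per_gene, panel_means, missing)


def delta_ct_expression(ct_gene: float, ct_reference: float) -> float:
    """Relative qPCR expression 2^-(Ct_gene - Ct_reference)."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_gene - ct_reference)


def cluster_expression(
    matrix: ExpressionMatrix,
    similarity: str = "uncentered_correlation",
    linkage: str = "average",
) -> SampleTree:
    """Hierarchical clustering of samples on log2(FPKM + 1)."""
    logged = np.log2(matrix.fpkm + 1.0)
    return cluster_samples(logged, similarity=similarity, linkage=linkage)
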