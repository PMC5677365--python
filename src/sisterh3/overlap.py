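"""Overlap of clusters with set1∆-responsive genes and pathway counting.

The K4R substitution mimics loss of K4 methylation but is not identical
to it; genes whose cluster assignment overlaps the set of genes altered
by deleting the SET1 methyltransferase are the ones most plausibly
regulated through methylation itself rather than the substitution.
Pathway membership of those overlap sets is counted from a user-supplied
gene -> pathway map (counts only, no enrichment statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ConfigError, DesignError
from .foldchange import FoldChangeTable, pooled_t_pvalues
from .gss import CLUSTER_I, CLUSTER_II, CLUSTER_III, GeneClassification
from .io import SET1D, WT, PathwayMap

UNMAPPED = "unmapped"


@dataclass(frozen=True)
class OverlapResult:
    set1_responsive: frozenset[str]
    intersections: dict[str, tuple[str, ...]]  # cluster -> sorted genes

    def size(self, cluster: str) -> int:
        return len(self.intersections.get(cluster, ()))


def set1_responsive_genes(fc: FoldChangeTable, alpha: float = 0.05) -> frozenset[str]:
    """Genes whose replicate FCs differ between the set1∆ strain and WT
    (pooled t-test, p < alpha)."""
    if not 0 <= alpha <= 1:
        raise ConfigError("alpha must be in [0, 1]")
    for role in (SET1D, WT):
        if role not in fc.strain_roles:
            raise DesignError(f"strain role {role!r} required for the set1∆ screen")
    kept = fc.kept_genes
    if not kept:
        return frozenset()
    p = pooled_t_pvalues(fc.strain_matrix(SET1D, kept), fc.strain_matrix(WT, kept))
    return frozenset(g for g, pv in zip(kept, p) if pv < alpha)


def intersect_clusters(
    classification: GeneClassification, set1: frozenset[str] | set[str]
) -> OverlapResult:
    """Intersect each cluster with the set1∆-responsive set; gene order
    in the output is lexicographic, so results are deterministic."""
    set1 = frozenset(set1)
    inter = {
        c: tuple(sorted(classification.cluster(c) & set1))
        for c in (CLUSTER_I, CLUSTER_II, CLUSTER_III)
    }
    return OverlapResult(set1_responsive=set1, intersections=inter)


def pathway_counts(
    genes: frozenset[str] | set[str], pmap: PathwayMap
) -> tuple[pd.DataFrame, int]:
    """Count genes per pathway label for one gene set.

    A gene belonging to several pathways counts toward each; genes with
    no mapping are tallied separately.  The table is sorted by count
    descending, ties broken by label.
    """
    counts: dict[str, int] = {}
    unmapped = 0
    for gene in genes:
        labels = pmap.pathways_of(gene)
        if not labels:
            unmapped += 1
            continue
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["pathway", "count"],
    )
    return table, unmapped


def overlap_frame(result: OverlapResult) -> pd.DataFrame:
    rows = [
        {"cluster": c, "gene_id": g}
        for c in (CLUSTER_I, CLUSTER_II, CLUSTER_III)
        for g in result.intersections.get(c, ())
    ]
    return pd.DataFrame(rows, columns=["cluster", "gene_id"])


def pathway_count_frame(
    result: OverlapResult, pmap: PathwayMap
) -> pd.DataFrame:
    """Per-intersection pathway counts in one long table, including an
    'unmapped' row per set."""
    rows = []
    for c in (CLUSTER_I, CLUSTER_II, CLUSTER_III):
        genes = set(result.intersections.get(c, ()))
        table, unmapped = pathway_counts(genes, pmap)
        set_name = f"{c}_and_set1"
        for _, r in table.iterrows():
            rows.append({"set_name": set_name, "pathway": r["pathway"], "count": r["count"]})
        rows.append({"set_name": set_name, "pathway": UNMAPPED, "count": unmapped})
    return pd.DataFrame(rows, columns=["set_name", "pathway", "count"])
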