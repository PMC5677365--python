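#!/usr/bin/env python
"""Overlap the clusters with set1∆-responsive genes and count pathways.

Genes whose cluster assignment also responds to deleting the SET1
methyltransferase are the ones attributable to K4 methylation itself
rather than to the K4R substitution.  Pathway membership of each
overlap set is counted from the (synthetic) gene -> pathway map.
"""

import json
from pathlib import Path

from sisterh3 import (
    average_fc,
    build_mid_set,
    classify_clusters,
    compute_fc,
    intersect_clusters,
    replicate_filter,
    screen_responsive,
    set1_responsive_genes,
)
from sisterh3.io import read_expression_matrix, read_pathway_map, read_sample_sheet
from sisterh3.overlap import pathway_count_frame

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SIM / "matrix.tsv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    matrix = read_expression_matrix(SIM / "matrix.tsv")
    design = read_sample_sheet(SIM / "samples.tsv")
    pmap = read_pathway_map(SIM / "pathways.tsv")

    fc = average_fc(replicate_filter(compute_fc(matrix, design)))
    responsive = screen_responsive(fc, alpha=0.05)
    mid = build_mid_set(fc, responsive)
    cl = classify_clusters(fc, mid, alpha=0.05)

    set1 = set1_responsive_genes(fc, alpha=0.05)
    overlap = intersect_clusters(cl, set1)

    print(f"set1∆-responsive genes: {len(set1)}")
    for c in ("I", "II", "III"):
        print(f"cluster {c}: {len(cl.cluster(c))} genes, "
              f"{overlap.size(c)} shared with set1∆")

    counts = pathway_count_frame(overlap, pmap)
    RESULTS.mkdir(exist_ok=True)
    counts.to_csv(RESULTS / "pathway_counts.tsv", sep="\t", index=False)
    top_ii = counts[counts["set_name"] == "II_and_set1"].head(4)
    print("top pathways in II ∩ set1∆:")
    for _, row in top_ii.iterrows():
        print(f"  {row['pathway']}: {row['count']}")

    with open(RESULTS / "overlap_summary.json", "w") as fh:
        json.dump({
            "n_set1_responsive": len(set1),
            "overlap_sizes": {c: overlap.size(c) for c in ("I", "II", "III")},
        }, fh, indent=2)
        fh.write("\n")


if __name__ == "__main__":
    main()
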