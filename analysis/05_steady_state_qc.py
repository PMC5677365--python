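#!/usr/bin/env python
"""Steady-state comparison of two strains before starvation.

The scatter of per-gene mean RPKM on the log10(mean + 1) scale, its
Pearson correlation, a through-origin fit with uncentered R², and the
two-fold / p ≤ 0.001 differential-expression filter — the standard
check that a mutant strain's baseline transcriptome matches its parent.
"""

import json
from pathlib import Path

from sisterh3 import de_filter, steady_state_comparison
from sisterh3.io import DOUBLE, WT, read_expression_matrix, read_sample_sheet

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SIM / "matrix.tsv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    matrix = read_expression_matrix(SIM / "matrix.tsv")
    design = read_sample_sheet(SIM / "samples.tsv")

    report = steady_state_comparison(matrix, design, WT, DOUBLE, timepoint="T0")
    de = de_filter(matrix, design, WT, DOUBLE, fold=2.0, p_cut=0.001)

    print(f"WT vs DOUBLE at T0 over {report.n_genes_compared} genes:")
    print(f"  Pearson r = {report.pearson_r:.4f}")
    print(f"  through-origin slope = {report.origin_slope:.4f}, "
          f"uncentered R^2 = {report.r_squared_uncentered:.4f}")
    print(f"  DE (>=2-fold, p<=0.001): {len(de.up)} up, {len(de.down)} down")

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "qc.json", "w") as fh:
        json.dump({**report.as_dict(), **de.as_dict()}, fh, indent=2)
        fh.write("\n")


if __name__ == "__main__":
    main()
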