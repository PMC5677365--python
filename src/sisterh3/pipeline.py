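"""End-to-end orchestration: fold-changes -> screen -> MID -> clusters
-> set1∆ overlap -> pathway counts, with provenance-stamped outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ConfigError
from .foldchange import (
    average_fc,
    compute_fc,
    foldchange_frame,
    replicate_filter,
    screen_responsive,
)
from .gss import build_mid_set, classify_clusters
from .io import (
    SET1D,
    ExpressionMatrix,
    PathwayMap,
    SampleDesign,
    validate_inputs,
)
from .overlap import (
    intersect_clusters,
    overlap_frame,
    pathway_count_frame,
    set1_responsive_genes,
)

log = logging.getLogger("sisterh3")


@dataclass
class RunConfig:
    """All knobs of a pipeline run, serializable for provenance."""

    out_dir: str = "results"
    reference_gene: str = "ACT1"
    alpha: float = 0.05
    mid_tolerance: float = 1e-9
    replicate_filter_method: str = "abs_diff"
    replicate_filter_threshold: float = 1.0
    pseudocount: float | None = None
    de_fold: float = 2.0
    de_p_cut: float = 0.001
    pooled_gss_bounds: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.de_fold < 1:
            raise ConfigError("de_fold must be >= 1")

    def hash(self) -> str:
        """Hash of the analysis-relevant parameters (output location is
        provenance-neutral, so identical analyses hash identically)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    fc_table: object
    responsive: object
    mid_set: frozenset
    classification: object
    overlap: object | None
    summary: dict


def _stamp(config: RunConfig) -> str:
    return f"sisterh3 v{__version__} config={config.hash()}"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, **to_csv) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_stamp(config)}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n", **to_csv)


def run_pipeline(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    config: RunConfig,
    pathway_map: PathwayMap | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the whole starvation analysis and (optionally) write result
    tables plus a summary JSON under ``config.out_dir``."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    findings = validate_inputs(matrix, design)
    for f in findings:
        if f.code in ("missing_sample", "reference_missing", "reference_zero"):
            log.warning("validation: %s", f)

    fc = compute_fc(matrix, design, pseudocount=config.pseudocount)
    fc = replicate_filter(
        fc,
        method=config.replicate_filter_method,
        threshold=config.replicate_filter_threshold,
    )
    fc = average_fc(fc)
    log.info(
        "fold-changes: %d genes, %d excluded", len(fc.genes), len(fc.exclusions)
    )

    responsive = screen_responsive(fc, alpha=config.alpha)
    mid_set = build_mid_set(fc, responsive, tol=config.mid_tolerance)
    classification = classify_clusters(
        fc,
        mid_set,
        alpha=config.alpha,
        mid_tol=config.mid_tolerance,
        pooled_bounds=config.pooled_gss_bounds,
    )
    counts = classification.counts
    log.info(
        "responsive=%d MID=%d clusters I/II/III = %d/%d/%d",
        len(responsive), len(mid_set),
        counts["I"], counts["II"], counts["III"],
    )

    overlap = None
    if SET1D in fc.strain_roles:
        set1 = set1_responsive_genes(fc, alpha=config.alpha)
        overlap = intersect_clusters(classification, set1)
        log.info(
            "set1∆-responsive=%d overlaps I/II/III = %d/%d/%d",
            len(set1),
            overlap.size("I"), overlap.size("II"), overlap.size("III"),
        )

    summary = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_genes": len(fc.genes),
        "n_excluded": len(fc.exclusions),
        "n_responsive": len(responsive),
        "n_mid": len(mid_set),
        "cluster_sizes": counts,
        "gss_max": classification.gss_max,
        "gss_min": classification.gss_min,
        "alpha": config.alpha,
        "mid_tolerance": config.mid_tolerance,
        "seed": config.seed,
    }
    if overlap is not None:
        summary["set1_overlap_sizes"] = {
            c: overlap.size(c) for c in ("I", "II", "III")
        }
        summary["n_set1_responsive"] = len(overlap.set1_responsive)

    if write:
        _write_tsv(foldchange_frame(fc), out / "foldchange.tsv", config, index=False)
        _write_tsv(classification.table, out / "classification.tsv", config)
        if overlap is not None:
            _write_tsv(overlap_frame(overlap), out / "overlap.tsv", config, index=False)
            if pathway_map is not None:
                _write_tsv(
                    pathway_count_frame(overlap, pathway_map),
                    out / "pathway_counts.tsv",
                    config,
                    index=False,
                )
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        fc_table=fc,
        responsive=responsive,
        mid_set=mid_set,
        classification=classification,
        overlap=overlap,
        summary=summary,
    )
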