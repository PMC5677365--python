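"""Synthetic expression data with planted sister-tail regulatory modes.

Emulates the five-strain, two-timepoint, duplicate starvation design:
~6000 yeast genes including a constant ACT1 reference, with a planted
regulatory mode per gene.  For a responsive gene the WT and DOUBLE
strains get distinct true log2 fold-changes (|difference| drawn from an
effect-size distribution), and the asymmetric strains follow the mode:

    COOPERATIVE  — asym FC = DOUBLE FC   (one missing mark is as bad as two)
    REDUNDANT    — asym FC = WT FC       (one remaining mark suffices)
    INDEPENDENT  — asym FC = λ·WT + (1−λ)·DOUBLE, λ ∈ (0, 1)
    NULL         — all strains share one FC

The set1∆ strain phenocopies the DOUBLE strain for a configurable
fraction of responsive genes (its effects act through the same
methylation) and is WT-like otherwise.

RPKM values are 2**(baseline + planted shift + noise); replicate noise
is additive Gaussian on the log2 scale per gene × sample, scaled so the
*fold-change* noise has standard deviation exactly ``sigma``.  The
reference gene is noise-free with zero planted fold-change, so the
normalization step is exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .gss import CLUSTER_I, CLUSTER_II, CLUSTER_III
from .io import (
    ASYM_A,
    ASYM_B,
    DOUBLE,
    SET1D,
    STRAIN_ROLES,
    T0,
    T1,
    WT,
    ExpressionMatrix,
    SampleDesign,
)

NULL = "NULL"
COOPERATIVE = "COOPERATIVE"
INDEPENDENT = "INDEPENDENT"
REDUNDANT = "REDUNDANT"
MODES = (COOPERATIVE, INDEPENDENT, REDUNDANT)

CLUSTER_NONE = "NONE"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults encode the study scale: ~6000 genes of which roughly 2500
    respond to loss of K4 methylation, five strains, two timepoints,
    two replicates.  ``sigma`` is the standard deviation (log2 units)
    of a replicate fold-change around its planted value.
    """

    n_genes: int = 6000
    fraction_responsive: float = 0.4
    mode_proportions: dict = field(
        default_factory=lambda: {COOPERATIVE: 0.10, INDEPENDENT: 0.50, REDUNDANT: 0.40}
    )
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    effect_low: float = 1.0
    effect_high: float = 3.0
    sigma: float = 0.1
    reference_gene: str = "ACT1"
    reference_level: float = 1024.0
    lambda_independent: float = 0.5
    set1_overlap: float = 1.0
    zero_fraction: float = 0.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2 (reference gene included)")
        if not 0 <= self.fraction_responsive <= 1:
            raise ConfigError("fraction_responsive must be in [0, 1]")
        props = self.mode_proportions
        if set(props) != set(MODES):
            raise ConfigError(f"mode_proportions must cover exactly {MODES}")
        if any(p < 0 for p in props.values()):
            raise ConfigError("mode proportions must be nonnegative")
        if not math.isclose(sum(props.values()), 1.0, abs_tol=1e-9):
            raise ConfigError("mode proportions must sum to 1")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if not 0 < self.lambda_independent < 1:
            raise ConfigError("lambda_independent must be strictly in (0, 1)")
        if not 0 <= self.set1_overlap <= 1:
            raise ConfigError("set1_overlap must be in [0, 1]")
        if not 0 <= self.zero_fraction <= 1:
            raise ConfigError("zero_fraction must be in [0, 1]")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates")
        if self.effect_low <= 0 or self.effect_high < self.effect_low:
            raise ConfigError("effect sizes must satisfy 0 < low <= high")


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth: per-gene mode and true per-strain FC."""

    table: pd.DataFrame  # index gene_id; columns mode, fc_wt, fc_asym_a, ...

    def mode(self, gene: str) -> str:
        return str(self.table.loc[gene, "mode"])

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, TruthTable]:
    """Generate (matrix, design, truth) for one synthetic experiment.

    Deterministic given ``config.seed``: the same config yields
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    ref = config.reference_gene
    gene_ids = [ref] + [f"G{i:04d}" for i in range(1, n)]

    n_free = n - 1  # reference gene is always NULL with zero FC
    responsive = rng.random(n_free) < config.fraction_responsive
    mode_labels = np.array(MODES, dtype=object)
    probs = np.array([config.mode_proportions[m] for m in MODES])
    modes = np.full(n_free, NULL, dtype=object)
    n_resp = int(responsive.sum())
    modes[responsive] = rng.choice(mode_labels, size=n_resp, p=probs)

    # true fold-changes (log2 units)
    fc_wt = rng.normal(0.0, 1.0, size=n_free)
    effect = rng.uniform(config.effect_low, config.effect_high, size=n_free)
    sign = rng.choice([-1.0, 1.0], size=n_free)
    fc_dbl = np.where(responsive, fc_wt + sign * effect, fc_wt)
    lam = config.lambda_independent
    fc_asym = np.select(
        [modes == COOPERATIVE, modes == REDUNDANT, modes == INDEPENDENT],
        [fc_dbl, fc_wt, lam * fc_wt + (1.0 - lam) * fc_dbl],
        default=fc_wt,
    )
    overlap_draw = rng.random(n_free) < config.set1_overlap
    fc_set1 = np.where(responsive & overlap_draw, fc_dbl, fc_wt)

    truth = pd.DataFrame(
        {
            "mode": np.concatenate([[NULL], modes]),
            "fc_wt": np.concatenate([[0.0], fc_wt]),
            "fc_asym_a": np.concatenate([[0.0], fc_asym]),
            "fc_asym_b": np.concatenate([[0.0], fc_asym]),
            "fc_double": np.concatenate([[0.0], fc_dbl]),
            "fc_set1": np.concatenate([[0.0], fc_set1]),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    true_fc = {
        WT: fc_wt,
        ASYM_A: fc_asym,
        ASYM_B: fc_asym,
        DOUBLE: fc_dbl,
        SET1D: fc_set1,
    }

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_free)
    # per-sample noise sd sigma/sqrt(2): an FC subtracts two sample
    # noises, so the FC noise sd comes out at exactly sigma
    noise_sd = config.sigma / math.sqrt(2.0)

    design_rows = []
    columns: dict[str, np.ndarray] = {}
    ref_log2 = math.log2(config.reference_level)
    for role in STRAIN_ROLES:
        for rep in range(1, config.n_replicates + 1):
            for tp in (T0, T1):
                sample_id = f"{role}_{tp}_r{rep}"
                design_rows.append(
                    {
                        "sample_id": sample_id,
                        "strain_role": role,
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
                shift = true_fc[role] if tp == T1 else 0.0
                noise = rng.normal(0.0, noise_sd, n_free) if noise_sd > 0 else 0.0
                log2_vals = baseline + shift + noise
                col = np.empty(n)
                col[0] = 2.0 ** ref_log2
                col[1:] = np.exp2(log2_vals)
                columns[sample_id] = col

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))

    if config.zero_fraction > 0:
        hit = 1 + np.flatnonzero(rng.random(n_free) < config.zero_fraction)
        if hit.size:
            sample_idx = rng.integers(0, values.shape[1], size=hit.size)
            arr = values.to_numpy()
            arr[hit, sample_idx] = 0.0
            values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    matrix = ExpressionMatrix(values)
    design = SampleDesign(pd.DataFrame(design_rows), reference_gene=ref)
    return matrix, design, TruthTable(truth)


def truth_cluster(truth: TruthTable) -> dict[str, str]:
    """Expected cluster per gene under perfect recovery: COOPERATIVE
    genes belong in Cluster I, INDEPENDENT in II, REDUNDANT in III,
    NULL genes in no cluster."""
    lut = {
        COOPERATIVE: CLUSTER_I,
        INDEPENDENT: CLUSTER_II,
        REDUNDANT: CLUSTER_III,
        NULL: CLUSTER_NONE,
    }
    return {g: lut[truth.mode(g)] for g in truth.genes}


# A handful of yeast-flavored pathway labels for the synthetic map.  The
# first three mirror the glycometabolism pathways a starvation response
# touches; the rest are generic background.
GLYCO_PATHWAYS = (
    "Carbon metabolism",
    "Citrate cycle (TCA cycle)",
    "Fructose and mannose metabolism",
)
OTHER_PATHWAYS = (
    "Ribosome biogenesis",
    "Oxidative phosphorylation",
    "Amino acid biosynthesis",
    "Autophagy",
    "MAPK signaling",
)


def simulate_pathway_map(
    truth: TruthTable,
    seed: int = 0,
    p_mapped_independent: float = 0.8,
    p_mapped_other: float = 0.4,
):
    """Synthetic gene -> pathway map (no real KEGG annotation involved).

    INDEPENDENT-mode genes are preferentially assigned to
    glycometabolism labels, other genes to background labels, mirroring
    a design where fine-tuned stress genes sit in carbon metabolism.
    """
    from .io import PathwayMap

    rng = np.random.default_rng(seed)
    mapping: dict[str, frozenset[str]] = {}
    for gene in truth.genes:
        mode = truth.mode(gene)
        if mode == INDEPENDENT:
            if rng.random() < p_mapped_independent:
                mapping[gene] = frozenset({GLYCO_PATHWAYS[rng.integers(len(GLYCO_PATHWAYS))]})
        else:
            if rng.random() < p_mapped_other:
                mapping[gene] = frozenset({OTHER_PATHWAYS[rng.integers(len(OTHER_PATHWAYS))]})
    return PathwayMap(mapping)


def write_truth_table(truth: TruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_truth_table(path) -> TruthTable:
    # keep_default_na: the literal mode string "NULL" is data, not NaN
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, keep_default_na=False)
    df.index = df.index.astype(str)
    return TruthTable(df)
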