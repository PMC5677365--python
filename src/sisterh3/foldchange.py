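"""Reference-normalized log2 fold-changes and the responsive-gene screen.

For gene *i*, strain *j*, replicate *r*, the induction fold-change under
glucose starvation is

    FC = log2( (RPKM_T1 / RPKM_T1_ref) / (RPKM_T0 / RPKM_T0_ref) )

where ``ref`` is the reference gene (ACT1 by default).  FCa is the mean
of the replicate FCs.  Genes with a zero RPKM in any used sample are
excluded (only genes with at least one mapped read in every sample carry
a defined ratio); genes whose replicates disagree beyond a configurable
criterion are excluded as irreproducible.  The responsive set collects
genes whose FCa differs significantly between the WT and the double
K4R mutant (pooled-variance Student t-test on the replicate FCs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DesignError, InputError
from .io import DOUBLE, ExpressionMatrix, SampleDesign, WT

ZERO_RPKM = "ZERO_RPKM"
REPLICATE_DISAGREEMENT = "REPLICATE_DISAGREEMENT"


@dataclass
class FoldChangeTable:
    """Per-replicate FCs, replicate means (FCa) and exclusion flags.

    ``fc`` is indexed by gene with a (strain_role, replicate)
    MultiIndex on the columns.  ``fca`` (gene x strain_role) is filled
    by :func:`average_fc` and stays None before that.  ``exclusions``
    maps excluded genes to a reason string.
    """

    fc: pd.DataFrame
    fca: pd.DataFrame | None = None
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.fc.index)

    @property
    def kept_genes(self) -> list[str]:
        return [g for g in self.fc.index if g not in self.exclusions]

    @property
    def strain_roles(self) -> list[str]:
        return sorted({role for role, _ in self.fc.columns})

    def replicate_fcs(self, gene: str, role: str) -> np.ndarray:
        """Replicate FC vector for one gene in one strain."""
        return self.fc.loc[gene, role].to_numpy(dtype=float)

    def strain_matrix(self, role: str, genes=None) -> np.ndarray:
        """(n_genes, n_replicates) FC array for one strain role."""
        sub = self.fc[role]
        if genes is not None:
            sub = sub.loc[genes]
        return sub.to_numpy(dtype=float)


@dataclass(frozen=True)
class ResponsiveSet:
    """Genes whose FCa responds to loss of both sister K4 marks
    (WT vs DOUBLE screen), with the screen's per-gene p-values."""

    genes: frozenset[str]
    pvalues: pd.Series  # over all screened (non-excluded) genes
    alpha: float

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def compute_fc(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    pseudocount: float | None = None,
) -> FoldChangeTable:
    """Compute per-replicate reference-normalized log2 fold-changes.

    Replicate r at T1 is paired with replicate r at T0 of the same
    strain.  With ``pseudocount`` set, that value is added to every RPKM
    before forming ratios (and the zero-RPKM exclusion is moot);
    otherwise genes with RPKM = 0 in any used sample are excluded with
    reason ``ZERO_RPKM``.
    """
    vals = matrix.values
    ref = design.reference_gene
    if ref not in vals.index:
        raise InputError(f"reference gene {ref!r} absent from matrix")

    pairs: dict[tuple[str, int], tuple[str, str]] = {}
    for role in design.roles:
        for rep, s0, s1 in design.paired_replicates(role):
            for s in (s0, s1):
                if s not in vals.columns:
                    raise DesignError(f"design sample {s!r} absent from matrix")
            pairs[(role, rep)] = (s0, s1)
    if not pairs:
        raise DesignError("no paired (T0, T1) replicates in the design")

    used_samples = sorted({s for p in pairs.values() for s in p})
    sub = vals[used_samples]
    if pseudocount is not None:
        if pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        sub = sub + pseudocount

    ref_vals = sub.loc[ref]
    if (ref_vals <= 0).any():
        bad = [s for s, v in ref_vals.items() if v <= 0]
        raise InputError(f"reference gene {ref!r} has RPKM 0 in samples {bad}")

    exclusions: dict[str, str] = {}
    if pseudocount is None:
        zero_mask = (sub == 0).any(axis=1)
        for g in sub.index[zero_mask]:
            if g != ref:
                exclusions[str(g)] = ZERO_RPKM

    cols = {}
    for (role, rep), (s0, s1) in sorted(pairs.items()):
        ratio1 = sub[s1] / ref_vals[s1]
        ratio0 = sub[s0] / ref_vals[s0]
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[(role, rep)] = np.log2(ratio1 / ratio0)
    fc = pd.DataFrame(cols, index=sub.index)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["strain_role", "replicate"])
    if exclusions:
        # excluded genes keep NaN FCs rather than infinities
        block = fc.loc[list(exclusions), :]
        fc.loc[list(exclusions), :] = block.where(np.isfinite(block))
    return FoldChangeTable(fc=fc, exclusions=exclusions)


def replicate_filter(
    fc: FoldChangeTable, method: str = "abs_diff", threshold: float = 1.0
) -> FoldChangeTable:
    """Mark genes whose replicate FCs disagree as excluded.

    The default (and only built-in) criterion flags a gene when the
    spread of its replicate FCs, max - min within any strain role,
    exceeds ``threshold`` log2 units.  This is a transparent, monotone
    surrogate for "the two independent experiments disagree".
    """
    if method != "abs_diff":
        raise ConfigError(f"unknown replicate-filter method {method!r}")
    if threshold < 0:
        raise ConfigError("replicate-filter threshold must be >= 0")
    exclusions = dict(fc.exclusions)
    spread = fc.fc.T.groupby(level="strain_role").agg(
        lambda x: x.max() - x.min()
    ).T
    worst = spread.max(axis=1)
    for gene, w in worst.items():
        if gene in exclusions:
            continue
        if np.isfinite(w) and w > threshold:
            exclusions[str(gene)] = REPLICATE_DISAGREEMENT
    return FoldChangeTable(fc=fc.fc, fca=None, exclusions=exclusions)


def average_fc(fc: FoldChangeTable) -> FoldChangeTable:
    """Fill FCa = arithmetic mean of replicate FCs for kept genes."""
    fca = fc.fc.T.groupby(level="strain_role").mean().T
    fca = fca.drop(index=[g for g in fc.exclusions if g in fca.index])
    return FoldChangeTable(fc=fc.fc, fca=fca, exclusions=dict(fc.exclusions))


def student_t_two_sample(a, b) -> float:
    """Two-sided pooled-variance Student t-test p-value.

    With tiny groups (two replicates) the pooled variance can vanish:
    then p = 1.0 if the group means coincide and 0.0 otherwise, so the
    screen stays well-defined in the noise-free limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    return float(
        pooled_t_pvalues(a.reshape(1, -1), b.reshape(1, -1))[0]
    )


def pooled_t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance two-sided t-test for (n, k) arrays.

    Degenerate rows (zero pooled variance) get p = 1 for equal means and
    p = 0 otherwise.  Rows containing NaN propagate NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs at least 2 values")
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    ss1 = ((a - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((b - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    nan_rows = np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1)
    p = np.where(nan_rows, np.nan, p)
    return p


def screen_responsive(fc: FoldChangeTable, alpha: float = 0.05) -> ResponsiveSet:
    """Screen for K4-methylation-responsive genes.

    A gene enters the responsive set when its WT replicate FCs differ
    from its DOUBLE replicate FCs at p < alpha (Student t-test).
    Excluded genes never enter.
    """
    if not 0 <= alpha <= 1:
        raise ConfigError("alpha must be in [0, 1]")
    for role in (WT, DOUBLE):
        if role not in fc.strain_roles:
            raise DesignError(f"strain role {role!r} required for the screen")
    kept = fc.kept_genes
    if not kept:
        return ResponsiveSet(frozenset(), pd.Series(dtype=float), alpha)
    p = pooled_t_pvalues(fc.strain_matrix(WT, kept), fc.strain_matrix(DOUBLE, kept))
    pvalues = pd.Series(p, index=kept, name="p_wt_vs_double")
    members = frozenset(pvalues.index[pvalues < alpha].astype(str))
    return ResponsiveSet(members, pvalues, alpha)


def foldchange_frame(fc: FoldChangeTable) -> pd.DataFrame:
    """Long-form result table: one row per gene with per-strain replicate
    FCs, FCa, and exclusion status."""
    rows = []
    roles = fc.strain_roles
    for gene in fc.genes:
        row: dict = {"gene_id": gene}
        for role in roles:
            vals = fc.replicate_fcs(gene, role)
            for i, v in enumerate(vals, start=1):
                row[f"fc_{role.lower()}_rep{i}"] = v
            if fc.fca is not None and gene in fc.fca.index:
                row[f"fca_{role.lower()}"] = fc.fca.loc[gene, role]
        row["excluded"] = gene in fc.exclusions
        row["reason"] = fc.exclusions.get(gene, "")
        rows.append(row)
    return pd.DataFrame(rows)


def _df2_tail_closed_form(t: float) -> float:
    """Closed-form two-sided tail of Student's t with 2 degrees of
    freedom: P(|T| > t) = 1 - t / sqrt(2 + t^2).  Kept for cross-checks
    against the numeric path."""
    return 1.0 - t / math.sqrt(2.0 + t * t)
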