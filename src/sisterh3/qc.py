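"""Steady-state two-strain comparison and differential-expression filter.

Quality control for a new strain: scatter its per-gene mean RPKM against
a reference strain's on the log10(mean + 1) scale, report the Pearson
correlation, a through-origin linear fit (slope = Σxy/Σx²) with the
uncentered R² = 1 − Σ(y − βx)²/Σy², and list genes passing a ≥ fold
change plus p ≤ p_cut differential-expression filter.  The DE p-value
is a per-gene Student t-test on log2(RPKM + 0.5) across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DesignError, InsufficientDataError
from .foldchange import pooled_t_pvalues
from .io import ExpressionMatrix, SampleDesign, T0


@dataclass
class QCReport:
    pearson_r: float
    origin_slope: float
    r_squared_uncentered: float
    n_genes_compared: int
    method_notes: str = (
        "Pearson r and through-origin fit on log10(mean RPKM + 1); "
        "uncentered R-squared"
    )

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "origin_slope": self.origin_slope,
            "r_squared": self.r_squared_uncentered,
            "n_genes": self.n_genes_compared,
            "method_notes": self.method_notes,
        }


@dataclass
class DEResult:
    up: tuple[str, ...]  # higher in strain_b
    down: tuple[str, ...]  # lower in strain_b
    table: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {"n_de_up": len(self.up), "n_de_down": len(self.down)}


def _strain_means(
    matrix: ExpressionMatrix, design: SampleDesign, strain: str, timepoint: str
) -> pd.DataFrame:
    t = design.table
    samples = t.loc[
        (t["strain_role"] == strain) & (t["timepoint"] == timepoint), "sample_id"
    ].tolist()
    if not samples:
        raise DesignError(f"no samples for strain {strain!r} at {timepoint}")
    missing = [s for s in samples if s not in matrix.values.columns]
    if missing:
        raise DesignError(f"design samples absent from matrix: {missing}")
    return matrix.values[samples]


def steady_state_comparison(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    strain_a: str,
    strain_b: str,
    timepoint: str = T0,
) -> QCReport:
    """Compare two strains' steady-state expression profiles.

    x = log10(mean RPKM of strain_a + 1), y likewise for strain_b.
    Reports Pearson r, the slope of the least-squares line through the
    origin, and the uncentered R² of that fit.
    """
    a = _strain_means(matrix, design, strain_a, timepoint).mean(axis=1)
    b = _strain_means(matrix, design, strain_b, timepoint).mean(axis=1)
    x = np.log10(a.to_numpy(dtype=float) + 1.0)
    y = np.log10(b.to_numpy(dtype=float) + 1.0)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 genes for the comparison")
    sxx = float(np.dot(x, x))
    if sxx == 0.0 or np.std(x) == 0.0 or np.std(y) == 0.0:
        raise InsufficientDataError("degenerate expression values (no variance)")
    r = float(stats.pearsonr(x, y).statistic)
    beta = float(np.dot(x, y) / sxx)
    resid = y - beta * x
    syy = float(np.dot(y, y))
    r2 = 1.0 - float(np.dot(resid, resid)) / syy
    return QCReport(
        pearson_r=r,
        origin_slope=beta,
        r_squared_uncentered=r2,
        n_genes_compared=int(x.size),
    )


def de_filter(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    strain_a: str,
    strain_b: str,
    fold: float = 2.0,
    p_cut: float = 0.001,
    timepoint: str = T0,
    pseudocount: float = 0.5,
) -> DEResult:
    """Differential-expression filter between two strains.

    A gene is DE when |log2(mean_b + ε) − log2(mean_a + ε)| ≥ log2(fold)
    AND a Student t-test on log2(RPKM + ε) across replicates gives
    p ≤ p_cut.  Direction is the sign of the log-ratio (up = higher in
    ``strain_b``).
    """
    if fold < 1:
        raise ConfigError("fold threshold must be >= 1")
    A = _strain_means(matrix, design, strain_a, timepoint)
    B = _strain_means(matrix, design, strain_b, timepoint)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise DesignError("need >= 2 replicates per strain for the DE t-test")
    la = np.log2(A.to_numpy(dtype=float) + pseudocount)
    lb = np.log2(B.to_numpy(dtype=float) + pseudocount)
    diff = np.log2(B.mean(axis=1).to_numpy() + pseudocount) - np.log2(
        A.mean(axis=1).to_numpy() + pseudocount
    )
    p = pooled_t_pvalues(lb, la)
    passes = (np.abs(diff) >= np.log2(fold)) & (p <= p_cut)
    genes = np.asarray(A.index, dtype=object)
    up = tuple(sorted(genes[passes & (diff > 0)]))
    down = tuple(sorted(genes[passes & (diff < 0)]))
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "log2_ratio": diff,
            "p_value": p,
            "de": passes,
            "direction": np.where(diff > 0, "up", np.where(diff < 0, "down", "none")),
        }
    )
    return DEResult(up=up, down=down, table=table)
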