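"""Mid betweenness statistic, gene skewness score (GSS), and the
Cluster I / II / III regulatory-mode classification.

The question the statistics answer: when the K4R substitution removes
methylation from only one of the two sister H3 tails, does a gene's
starvation fold-change look like the wild type (redundant marks), like
the double mutant (cooperative marks), or land strictly in between
(independent, additive marks)?

For a responsive gene with strain averages FCa:

    Mid = (|FCa_asym - FCa_WT| + |FCa_asym - FCa_DOUBLE|)
          / |FCa_WT - FCa_DOUBLE|

Mid >= 1 always (triangle inequality) and Mid = 1 exactly when the
asymmetric-strain value lies in the closed interval between the WT and
DOUBLE values.  Genes with Mid = 1 in both asymmetric strains form the
MID subset, on which the skewness score is defined:

    GSS = log2( |FCa_asym - FCa_DOUBLE| / |FCa_asym - FCa_WT| )

GSS > 0 means the asymmetric strain skews toward WT, GSS < 0 toward the
double mutant; GSS is +inf when the asymmetric value equals the WT value
and -inf when it equals the DOUBLE value (extended-real contract).

Clusters are then carved out of MID with pooled-variance t-tests on the
replicate FCs (each asymmetric strain vs WT and vs DOUBLE):

    II  — significantly different from both endpoints (independent);
          the min/max finite GSS over its members set GSS_min/GSS_max
    III — indistinguishable from WT, different from DOUBLE,
          GSS > GSS_max (redundant)
    I   — different from WT, indistinguishable from DOUBLE,
          GSS < GSS_min (cooperative)

applied in the order II -> bounds -> III -> I, each condition required
of BOTH asymmetric strains; everything else stays UNASSIGNED.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ClassificationWarning,
    ConfigError,
    DegenerateEndpointsError,
)
from .foldchange import FoldChangeTable, ResponsiveSet, pooled_t_pvalues
from .io import ASYM_A, ASYM_B, DOUBLE, WT

CLUSTER_I = "I"
CLUSTER_II = "II"
CLUSTER_III = "III"
UNASSIGNED = "UNASSIGNED"

DEFAULT_MID_TOL = 1e-9


@dataclass
class GeneClassification:
    """Classification result over the MID subset.

    ``table`` is indexed by gene with columns fca_wt, fca_asym_a,
    fca_asym_b, fca_double, mid_a, mid_b, gss_a, gss_b, p_wt_a, p_dbl_a,
    p_wt_b, p_dbl_b, cluster.  ``gss_max``/``gss_min`` are the Cluster II
    bounds (None when Cluster II is empty)."""

    table: pd.DataFrame
    gss_max: float | None
    gss_min: float | None
    alpha: float
    mid_set: frozenset[str]

    def cluster(self, name: str) -> frozenset[str]:
        t = self.table
        return frozenset(t.index[t["cluster"] == name].astype(str))

    @property
    def counts(self) -> dict[str, int]:
        return {
            c: int((self.table["cluster"] == c).sum())
            for c in (CLUSTER_I, CLUSTER_II, CLUSTER_III, UNASSIGNED)
        }


def mid_statistic(
    fca_asym: float, fca_wt: float, fca_double: float, tol: float = 1e-12
) -> float:
    """Betweenness statistic; >= 1, and = 1 iff ``fca_asym`` lies in the
    closed interval between ``fca_wt`` and ``fca_double``."""
    span = abs(fca_wt - fca_double)
    if span <= tol * max(1.0, abs(fca_wt), abs(fca_double)):
        raise DegenerateEndpointsError(
            "WT and DOUBLE fold-changes coincide; Mid undefined"
        )
    return (abs(fca_asym - fca_wt) + abs(fca_asym - fca_double)) / span


def gss(fca_asym: float, fca_wt: float, fca_double: float) -> float:
    """Skewness score on the extended reals.

    Returns +inf when the asymmetric value equals the WT value (fully
    redundant) and -inf when it equals the DOUBLE value (fully
    cooperative)."""
    num = abs(fca_asym - fca_double)
    den = abs(fca_asym - fca_wt)
    if den == 0.0 and num == 0.0:
        raise DegenerateEndpointsError("all three fold-changes coincide")
    if den == 0.0:
        return math.inf
    if num == 0.0:
        return -math.inf
    return math.log2(num / den)


def _mid_frame(
    fc: FoldChangeTable, genes: list[str], tol: float
) -> tuple[pd.DataFrame, list[str]]:
    """Vectorized Mid for both asymmetric strains; returns the frame and
    the genes skipped for degenerate endpoints."""
    fca = fc.fca
    wt = fca.loc[genes, WT].to_numpy(dtype=float)
    dbl = fca.loc[genes, DOUBLE].to_numpy(dtype=float)
    a = fca.loc[genes, ASYM_A].to_numpy(dtype=float)
    b = fca.loc[genes, ASYM_B].to_numpy(dtype=float)
    span = np.abs(wt - dbl)
    scale = np.maximum(1.0, np.maximum(np.abs(wt), np.abs(dbl)))
    degenerate = span <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        mid_a = (np.abs(a - wt) + np.abs(a - dbl)) / span
        mid_b = (np.abs(b - wt) + np.abs(b - dbl)) / span
    frame = pd.DataFrame(
        {
            "fca_wt": wt,
            "fca_asym_a": a,
            "fca_asym_b": b,
            "fca_double": dbl,
            "mid_a": mid_a,
            "mid_b": mid_b,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    skipped = [g for g, d in zip(genes, degenerate) if d]
    frame = frame.drop(index=skipped)
    return frame, skipped


def build_mid_set(
    fc: FoldChangeTable,
    responsive: ResponsiveSet,
    tol: float = DEFAULT_MID_TOL,
) -> frozenset[str]:
    """MID subset: responsive genes whose Mid = 1 (within ``tol``) in
    BOTH asymmetric strains.  Genes with coincident WT/DOUBLE averages
    are skipped with a warning."""
    if fc.fca is None:
        raise ConfigError("FCa not filled; run average_fc first")
    genes = sorted(g for g in responsive.genes if g in fc.fca.index)
    if not genes:
        return frozenset()
    frame, skipped = _mid_frame(fc, genes, tol)
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene(s) skipped: WT and DOUBLE fold-changes "
            f"coincide (e.g. {skipped[0]!r})",
            ClassificationWarning,
            stacklevel=2,
        )
    ok = (frame["mid_a"] <= 1.0 + tol) & (frame["mid_b"] <= 1.0 + tol)
    return frozenset(frame.index[ok].astype(str))


def _gss_vector(asym: np.ndarray, wt: np.ndarray, dbl: np.ndarray) -> np.ndarray:
    num = np.abs(asym - dbl)
    den = np.abs(asym - wt)
    out = np.full(asym.shape, np.nan)
    both = (num == 0) & (den == 0)
    pos = (den == 0) & ~both
    neg = (num == 0) & ~both
    fin = ~(pos | neg | both)
    out[pos] = np.inf
    out[neg] = -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        out[fin] = np.log2(num[fin] / den[fin])
    return out


def classify_clusters(
    fc: FoldChangeTable,
    mid_set: frozenset[str] | set[str],
    alpha: float = 0.05,
    mid_tol: float = DEFAULT_MID_TOL,
    pooled_bounds: bool = True,
) -> GeneClassification:
    """Assign every MID gene to Cluster I, II, III or UNASSIGNED.

    ``pooled_bounds`` pools GSS values from both asymmetric strains of
    Cluster II members into one set before taking GSS_max/GSS_min; with
    False the bounds (and the III/I comparisons) are per-strain.
    """
    if fc.fca is None:
        raise ConfigError("FCa not filled; run average_fc first")
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must be in (0, 1]")
    genes = sorted(mid_set)
    columns = [
        "fca_wt", "fca_asym_a", "fca_asym_b", "fca_double",
        "mid_a", "mid_b", "gss_a", "gss_b",
        "p_wt_a", "p_dbl_a", "p_wt_b", "p_dbl_b", "cluster",
    ]
    if not genes:
        warnings.warn(
            "MID subset is empty; nothing to classify",
            ClassificationWarning,
            stacklevel=2,
        )
        empty = pd.DataFrame(columns=columns)
        empty.index.name = "gene_id"
        return GeneClassification(empty, None, None, alpha, frozenset())

    frame, _ = _mid_frame(fc, genes, mid_tol)
    wt = frame["fca_wt"].to_numpy()
    dbl = frame["fca_double"].to_numpy()
    frame["gss_a"] = _gss_vector(frame["fca_asym_a"].to_numpy(), wt, dbl)
    frame["gss_b"] = _gss_vector(frame["fca_asym_b"].to_numpy(), wt, dbl)

    idx = list(frame.index)
    fcs = {role: fc.strain_matrix(role, idx) for role in (WT, ASYM_A, ASYM_B, DOUBLE)}
    frame["p_wt_a"] = pooled_t_pvalues(fcs[ASYM_A], fcs[WT])
    frame["p_dbl_a"] = pooled_t_pvalues(fcs[ASYM_A], fcs[DOUBLE])
    frame["p_wt_b"] = pooled_t_pvalues(fcs[ASYM_B], fcs[WT])
    frame["p_dbl_b"] = pooled_t_pvalues(fcs[ASYM_B], fcs[DOUBLE])

    sig_wt_a = frame["p_wt_a"] < alpha
    sig_dbl_a = frame["p_dbl_a"] < alpha
    sig_wt_b = frame["p_wt_b"] < alpha
    sig_dbl_b = frame["p_dbl_b"] < alpha

    in_ii = sig_wt_a & sig_dbl_a & sig_wt_b & sig_dbl_b

    cluster = pd.Series(UNASSIGNED, index=frame.index, name="cluster")
    cluster[in_ii] = CLUSTER_II

    gss_a = frame["gss_a"]
    gss_b = frame["gss_b"]
    ii_gss = np.concatenate([gss_a[in_ii].to_numpy(), gss_b[in_ii].to_numpy()])
    finite = ii_gss[np.isfinite(ii_gss)]
    if finite.size == 0:
        warnings.warn(
            "Cluster II is empty (or has no finite GSS); GSS bounds "
            "undefined, Clusters I and III left UNASSIGNED",
            ClassificationWarning,
            stacklevel=2,
        )
        gss_max = gss_min = None
    else:
        if pooled_bounds:
            gss_max = float(finite.max())
            gss_min = float(finite.min())
        else:
            fa = gss_a[in_ii].to_numpy()
            fb = gss_b[in_ii].to_numpy()
            gss_max = (
                float(np.nanmax(fa[np.isfinite(fa)])),
                float(np.nanmax(fb[np.isfinite(fb)])),
            )
            gss_min = (
                float(np.nanmin(fa[np.isfinite(fa)])),
                float(np.nanmin(fb[np.isfinite(fb)])),
            )

    if gss_max is not None:
        if pooled_bounds:
            hi_a = gss_a > gss_max
            hi_b = gss_b > gss_max
            lo_a = gss_a < gss_min
            lo_b = gss_b < gss_min
        else:
            hi_a = gss_a > gss_max[0]
            hi_b = gss_b > gss_max[1]
            lo_a = gss_a < gss_min[0]
            lo_b = gss_b < gss_min[1]
        in_iii = (
            ~in_ii
            & ~sig_wt_a & sig_dbl_a & hi_a
            & ~sig_wt_b & sig_dbl_b & hi_b
        )
        cluster[in_iii] = CLUSTER_III
        in_i = (
            ~in_ii & ~in_iii
            & sig_wt_a & ~sig_dbl_a & lo_a
            & sig_wt_b & ~sig_dbl_b & lo_b
        )
        cluster[in_i] = CLUSTER_I

    frame["cluster"] = cluster
    frame = frame[columns]
    gmax = gss_max if pooled_bounds or gss_max is None else max(gss_max)
    gmin = gss_min if pooled_bounds or gss_min is None else min(gss_min)
    return GeneClassification(
        table=frame,
        gss_max=gmax,
        gss_min=gmin,
        alpha=alpha,
        mid_set=frozenset(genes),
    )
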