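"""Core data model: expression matrices, sample sheets, pathway maps.

All tabular inputs are UTF-8 tab-separated text; lines starting with ``#``
are comments.  Gene and sample identifiers are opaque, case-sensitive
strings (systematic names like ``YOR008C`` and common names like ``ACT1``
co-occur in yeast annotation, so no normalization is attempted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, PairingError, UniquenessError, DesignError

# Strain roles of the five-strain genotype series.  WT is the engineered
# H3 heterodimer strain that anchors the series; ASYM_A / ASYM_B carry the
# K4R substitution on one sister H3 tail, DOUBLE on both, SET1D lacks the
# H3K4 methyltransferase.
WT = "WT"
ASYM_A = "ASYM_A"
ASYM_B = "ASYM_B"
DOUBLE = "DOUBLE"
SET1D = "SET1D"
OTHER = "OTHER"
STRAIN_ROLES = (WT, ASYM_A, ASYM_B, DOUBLE, SET1D)

T0 = "T0"
T1 = "T1"
TIMEPOINTS = (T0, T1)

DEFAULT_REFERENCE_GENE = "ACT1"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample table of nonnegative RPKM values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample
        identifiers as columns.  Every cell must be finite and >= 0.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise UniquenessError(f"duplicate gene identifiers: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise UniquenessError(f"duplicate sample identifiers: {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid RPKM value {arr[i, j]!r} at gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r} "
                "(must be finite and >= 0)"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


@dataclass(frozen=True)
class SampleDesign:
    """Maps samples to (strain role, timepoint, replicate).

    ``table`` has columns ``sample_id``, ``strain_role``, ``timepoint``,
    ``replicate``.  ``reference_gene`` names the gene used for
    normalization of fold-changes (ACT1 by default, as is customary for
    yeast expression assays).
    """

    table: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        required = ["sample_id", "strain_role", "timepoint", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise UniquenessError(f"duplicate sample identifiers: {dup}")
        bad_tp = sorted(set(t["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise FormatError(f"unknown timepoints {bad_tp}; expected {TIMEPOINTS}")
        if (t["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")
        known = t[t["strain_role"] != OTHER]
        key = list(zip(known["strain_role"], known["timepoint"], known["replicate"]))
        seen: set = set()
        for k in key:
            if k in seen:
                raise DesignError(f"duplicate (strain_role, timepoint, replicate) {k}")
            seen.add(k)
        # every starved sample needs its unstarved partner
        for (role, rep), grp in known.groupby(["strain_role", "replicate"]):
            tps = set(grp["timepoint"])
            if T1 in tps and T0 not in tps:
                raise PairingError(
                    f"sample for ({role}, {T1}, replicate {rep}) has no "
                    f"matching {T0} sample"
                )

    @property
    def roles(self) -> list[str]:
        return sorted(set(self.table["strain_role"]) - {OTHER})

    def replicates(self, role: str) -> list[int]:
        sub = self.table[self.table["strain_role"] == role]
        return sorted(set(sub["replicate"].astype(int)))

    def sample_id(self, role: str, timepoint: str, replicate: int) -> str:
        t = self.table
        hit = t[
            (t["strain_role"] == role)
            & (t["timepoint"] == timepoint)
            & (t["replicate"].astype(int) == int(replicate))
        ]
        if len(hit) != 1:
            raise DesignError(
                f"no unique sample for ({role}, {timepoint}, replicate {replicate})"
            )
        return str(hit["sample_id"].iloc[0])

    def paired_replicates(self, role: str) -> list[tuple[int, str, str]]:
        """(replicate, T0 sample, T1 sample) for every paired replicate."""
        out = []
        for rep in self.replicates(role):
            sub = self.table[
                (self.table["strain_role"] == role)
                & (self.table["replicate"].astype(int) == rep)
            ]
            tps = dict(zip(sub["timepoint"], sub["sample_id"]))
            if T0 in tps and T1 in tps:
                out.append((rep, str(tps[T0]), str(tps[T1])))
        return out


@dataclass(frozen=True)
class PathwayMap:
    """Gene -> set of pathway labels; absent genes count as unmapped."""

    mapping: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, labels in self.mapping.items():
            for lab in labels:
                if not lab:
                    raise FormatError(f"empty pathway label for gene {gene!r}")

    def pathways_of(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())


@dataclass(frozen=True)
class Finding:
    """One validation finding: a machine code plus a human message."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample RPKM table.

    First column: gene identifiers; header row: sample identifiers.
    Raises :class:`FormatError` on missing/duplicated headers or bad cells.
    """
    path = Path(path)
    header = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split("\t")
            break
    if header is None or len(header) < 2:
        raise FormatError(f"{path}: missing or empty header row")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise UniquenessError(f"{path}: duplicate sample identifiers {dup}")
    df = _read_tsv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = sample_ids
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric cell {df.loc[gene, col]!r} at "
                f"gene {gene!r}, sample {col!r}"
            )
        # numpy's parser is correctly rounded; to_numeric's fast path is not
        numeric[col] = df[col].to_numpy(dtype="U32").astype(float)
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a matrix as TSV; float repr is shortest-roundtrip, so a
    write/read cycle reproduces identifiers and values exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.values.to_csv(
            fh,
            sep="\t",
            index_label="gene_id",
            lineterminator="\n",
            float_format=lambda v: format(v, ".17g"),
        )


def read_sample_sheet(
    path: str | Path, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> SampleDesign:
    """Read a sample sheet with columns sample_id / strain_role /
    timepoint / replicate.  Unknown strain roles map to OTHER with a
    warning; they are carried along but never analyzed."""
    df = _read_tsv(path, dtype=str)
    required = ["sample_id", "strain_role", "timepoint", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    unknown = sorted(set(df["strain_role"]) - set(STRAIN_ROLES) - {OTHER})
    if unknown:
        warnings.warn(
            f"unknown strain roles {unknown} mapped to {OTHER}", stacklevel=2
        )
        df = df.copy()
        df.loc[df["strain_role"].isin(unknown), "strain_role"] = OTHER
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer replicate field ({exc})") from None
    return SampleDesign(df.reset_index(drop=True), reference_gene=reference_gene)


def write_sample_sheet(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a two-column gene_id / pathway_label TSV (one row per
    membership; a gene may appear several times)."""
    df = _read_tsv(path, dtype=str, header=0)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError(f"{path}: pathway map needs gene_id and pathway_label")
    mapping: dict[str, set[str]] = {}
    for gene, label in zip(df[cols[0]], df[cols[1]]):
        gene = str(gene)
        if pd.isna(label) or not str(label).strip():
            mapping.setdefault(gene, set())
        else:
            mapping.setdefault(gene, set()).add(str(label))
    return PathwayMap({g: frozenset(s) for g, s in mapping.items()})


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    rows = []
    for gene in sorted(pmap.mapping):
        labels = sorted(pmap.mapping[gene])
        if not labels:
            continue
        rows.extend((gene, lab) for lab in labels)
    pd.DataFrame(rows, columns=["gene_id", "pathway_label"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def validate_inputs(matrix: ExpressionMatrix, design: SampleDesign) -> list[Finding]:
    """Report (without raising) every inconsistency that would bite the
    fold-change stage: design samples absent from the matrix, a missing
    or zero reference gene, and genes with zero RPKM in any used sample
    (such genes are later excluded, keeping only genes to which at least
    one read was mapped)."""
    findings: list[Finding] = []
    used_samples = [
        s for s, r in zip(design.table["sample_id"], design.table["strain_role"])
        if r != OTHER
    ]
    present = [s for s in used_samples if s in matrix.values.columns]
    for s in used_samples:
        if s not in matrix.values.columns:
            findings.append(Finding("missing_sample", f"sample {s!r} not in matrix"))
    ref = design.reference_gene
    if ref not in matrix.values.index:
        findings.append(
            Finding("reference_missing", f"reference gene {ref!r} not in matrix")
        )
    elif present:
        ref_vals = matrix.values.loc[ref, present]
        zero_in = [s for s, v in ref_vals.items() if v == 0]
        for s in zero_in:
            findings.append(
                Finding("reference_zero", f"reference gene {ref!r} has RPKM 0 in {s!r}")
            )
    if present:
        sub = matrix.values[present]
        zero_genes = sub.index[(sub == 0).any(axis=1)]
        for g in zero_genes:
            findings.append(
                Finding("zero_rpkm", f"gene {g!r} has RPKM 0 in a used sample")
            )
    return findings
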