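from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sisterh3 import (
    ExpressionMatrix,
    FoldChangeTable,
    SampleDesign,
    SimulationConfig,
    average_fc,
    simulate_experiment,
)
from sisterh3.io import ASYM_A, ASYM_B, DOUBLE, SET1D, T0, T1, WT

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ROLES = (WT, ASYM_A, ASYM_B, DOUBLE)


def make_matrix(values: dict[str, list[float]], genes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))
    )


def make_design(
    roles=ROLES, replicates=(1, 2), reference_gene: str = "ACT1"
) -> SampleDesign:
    rows = [
        {
            "sample_id": f"{role}_{tp}_r{rep}",
            "strain_role": role,
            "timepoint": tp,
            "replicate": rep,
        }
        for role in roles
        for rep in replicates
        for tp in (T0, T1)
    ]
    return SampleDesign(pd.DataFrame(rows), reference_gene=reference_gene)


def fc_table_from_arrays(
    genes: list[str], per_role: dict[str, np.ndarray]
) -> FoldChangeTable:
    """Build an averaged FoldChangeTable straight from replicate FC
    arrays (shape n_genes x n_replicates per strain role)."""
    cols = {}
    for role, arr in per_role.items():
        arr = np.asarray(arr, dtype=float)
        for r in range(arr.shape[1]):
            cols[(role, r + 1)] = arr[:, r]
    fc = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["strain_role", "replicate"])
    return average_fc(FoldChangeTable(fc=fc))


def random_fc_arrays(
    rng: np.random.Generator, n_genes: int, noise_lo=0.05, noise_hi=0.3
) -> dict[str, np.ndarray]:
    """Random replicate-FC fixture covering midpoints, endpoints and
    borderline genes (used by oracle-equivalence tests)."""
    wt = rng.uniform(-3, 3, n_genes)
    dbl = wt + rng.choice([-1, 1], n_genes) * rng.uniform(0.2, 3.0, n_genes)
    frac = rng.uniform(-0.2, 1.2, n_genes)  # some genes fall outside
    asym_a = wt + frac * (dbl - wt)
    asym_b = wt + (frac + rng.normal(0, 0.1, n_genes)) * (dbl - wt)
    sd = rng.uniform(noise_lo, noise_hi, n_genes)
    out = {}
    for role, center in ((WT, wt), (ASYM_A, asym_a), (ASYM_B, asym_b), (DOUBLE, dbl)):
        out[role] = center[:, None] + rng.normal(0, 1, (n_genes, 2)) * sd[:, None]
    return out


@pytest.fixture(scope="session")
def small_experiment():
    """One small synthetic experiment shared by read-only tests."""
    cfg = SimulationConfig(n_genes=300, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noise_free_experiment():
    cfg = SimulationConfig(n_genes=120, sigma=0.0, seed=5)
    return simulate_experiment(cfg)
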