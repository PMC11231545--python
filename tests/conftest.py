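import numpy as np
import pytest
from hypothesis import settings

from tgrisk import SimulationConfig, simulate_cohort
from tgrisk.variant_classification import GenotypeMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort5000():
    """One full-size synthetic cohort shared by distribution-level tests."""
    return simulate_cohort(SimulationConfig(n_participants=5000, seed=123))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast structural / round-trip tests."""
    return simulate_cohort(
        SimulationConfig(n_participants=250, seed=11, n_rare_variants_per_gene=10, n_prs_loci=30, n_causal_loci=15)
    )


def make_matrix(columns: dict[str, list[int]]) -> GenotypeMatrix:
    """Hand-built genotype matrix from {variant_id: dosage list}."""
    variant_ids = list(columns)
    n = len(next(iter(columns.values())))
    pids = [f"S{i}" for i in range(n)]
    dosages = np.array([columns[v] for v in variant_ids], dtype=np.int8).T
    return GenotypeMatrix(pids, variant_ids, dosages)
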