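import numpy as np
import pandas as pd
import pytest

from gxepi import Misreporters, SimulationConfig, SnpSpec, simulate_cohort
from gxepi.config import OutcomeEffects


def clean_config(**kwargs) -> SimulationConfig:
    """A config with no misreporters or missing outcomes, for tests that
    want every simulated row retained."""
    defaults = dict(misreporters=Misreporters(0, 0, 0, 0), n_missing_outcome=0)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def flat_panel(n_snps: int, maf: float = 0.3, gene: str = "SOCS3") -> list[SnpSpec]:
    return [SnpSpec(rsid=f"rs{i:03d}", gene=gene, maf=maf) for i in range(n_snps)]


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared across tests (seed 11)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_discrete_dataset(seed: int, n_factors: int = 2,
                            max_n: int = 30) -> tuple[pd.DataFrame, np.ndarray]:
    """Small random factor/outcome dataset for oracle-equivalence batteries."""
    r = np.random.default_rng(seed)
    n = int(r.integers(10, max_n + 1))
    while True:
        y = r.integers(0, 2, size=n)
        if 0 < y.sum() < n:
            break
    cols = {}
    for j in range(n_factors):
        k = int(r.integers(2, 4))
        while True:
            v = r.integers(0, k, size=n)
            if len(np.unique(v)) >= 2:
                break
        cols[f"f{j}"] = v
    return pd.DataFrame(cols), y
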