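import numpy as np
import pandas as pd
import pytest

from anxgwas.containers import GenotypeMatrix
from anxgwas.simulate import SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Structured two-population cohort reused across modules."""
    spec = SimulationSpec(
        n_samples=600,
        n_variants=500,
        n_populations=2,
        fst=0.1,
        n_causal=10,
        causal_effect_sd=0.4,
        missing_rate=0.01,
        seed=11,
    )
    G, table, truth = simulate_cohort(spec)
    return G, table, truth, spec


def make_matrix(dosages, filters=None, n_alt=None, alts=None):
    """Small GenotypeMatrix straight from a dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 10,
            "id": [f"v{i}" for i in range(m)],
            "ref": "A",
            "alt": alts if alts is not None else ["G"] * m,
            "filter": filters if filters is not None else ["PASS"] * m,
            "n_alt": n_alt if n_alt is not None else [1] * m,
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


@pytest.fixture
def matrix_factory():
    return make_matrix
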