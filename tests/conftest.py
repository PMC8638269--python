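import numpy as np
import pandas as pd
import pytest

from compocor.io import CountMatrix
from compocor.simulate import SimulationConfig, generate_dataset


def make_count_matrix(counts, genes=None, samples=None, origins=None, lengths=None):
    """Build a CountMatrix from a plain array with minimal annotation."""
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    origins = origins or ["nuclear"] * len(genes)
    lengths = lengths if lengths is not None else [1000] * len(genes)
    ann = pd.DataFrame(
        {"symbol": genes, "length_bp": lengths, "origin": origins}, index=genes
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), ann)


@pytest.fixture
def toy_cm():
    """3 genes x 2 samples with one mitochondrial gene and varied lengths."""
    return make_count_matrix(
        [[50, 100], [30, 10], [20, 90]],
        origins=["mitochondrial", "nuclear", "nuclear"],
        lengths=[500, 1000, 2000],
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Multi-cohort null data (no planted mito-nuclear correlation) at the
    default study conditions; shared across tests."""
    cfg = SimulationConfig(
        n_cohorts=3,
        samples_per_cohort=120,
        mt_fraction_mean=[0.1, 0.3, 0.6],
        mt_fraction_cv=0.3,
        rho_mt_nu=0.0,
        seed=0,
    )
    return generate_dataset(cfg)
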