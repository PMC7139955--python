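import logging

import numpy as np
import pandas as pd
import pytest

from immunosig import ExpressionMatrix, ModuleSpec, SimulationConfig, simulate_cohort

logging.getLogger("immunosig").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort with the standard three modules and survival."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def planted_config():
    """Three uncorrelated planted modules, no immune-activity shift, one
    cancer type — the clean planted-partition fixture."""

    def make(seed: int, within_corr: float = 0.9):
        return SimulationConfig(
            seed=seed,
            n_types=1,
            samples_per_type=300,
            active_fraction=0.0,
            n_background_genes=40,
            betas={},
            modules=[
                ModuleSpec("M1", 10, within_corr=within_corr),
                ModuleSpec("M2", 6, within_corr=within_corr),
                ModuleSpec("M3", 5, within_corr=within_corr),
            ],
        )

    return make


@pytest.fixture
def small_log2_matrix():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{j}" for j in range(10)]
    df = pd.DataFrame(
        rng.normal(6.0, 1.0, size=(8, 10)), index=genes, columns=samples
    )
    return ExpressionMatrix(df, scale="log2")


@pytest.fixture
def toy_survival():
    """Four subjects, one binary covariate, all events, distinct times.

    Groups interleave in time so the partial likelihood has a finite
    maximizer (a block ordering would be completely separated).
    """
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
            "group": [1.0, 0.0, 1.0, 0.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )
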