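import numpy as np
import pandas as pd
import pytest

from mmflowps.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """n=30 cohort with strong planted markers; fast enough for unit tests."""
    cfg = SimConfig(
        n_samples=30,
        n_genes=300,
        n_markers=10,
        responder_fraction=0.5,
        effect_log2fc=2.5,
        dispersion=0.1,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted signal (effect_log2fc = 0)."""
    cfg = SimConfig(
        n_samples=30,
        n_genes=300,
        n_markers=10,
        responder_fraction=0.5,
        effect_log2fc=0.0,
        dispersion=0.1,
        seed=12,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(1, 200, size=(20, 6)),
        index=[f"G{i}" for i in range(20)],
        columns=[f"S{j}" for j in range(6)],
    )
    counts.index.name = "gene"
    return counts
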