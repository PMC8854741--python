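import numpy as np
import pandas as pd
import pytest

from seedomics import SimulationConfig, simulate_experiment


def make_design(n_replicates=3, div_levels=(3, 7, 14), n_plates=4, assay="rna"):
    rows = []
    i = 0
    for div in div_levels:
        for treatment in ("seed", "control"):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{assay}_{treatment}_d{div}_r{rep}",
                        "treatment": treatment,
                        "div": div,
                        "replicate": rep,
                        "plate": f"P{i % n_plates + 1}",
                        "assay": assay,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def design18():
    """Balanced 2x3 design, 3 replicates per cell, 4 plates."""
    return make_design()


@pytest.fixture(scope="session")
def small_experiment():
    """A modest simulated experiment with spiked effects, reused read-only."""
    config = SimulationConfig(
        n_genes=400,
        archetype_fractions={
            "null": 0.7,
            "monotone_up": 0.1,
            "monotone_down": 0.1,
            "late_only": 0.07,
            "early_only": 0.03,
        },
        effect_size=2.0,
        residual_sd=0.25,
        plate_sd=0.0,
        n_plates=1,
        protein_fraction=0.5,
        concordant_fraction=1.0,
        protein_missing_rate=0.0,
        rng_seed=7,
    )
    return simulate_experiment(config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
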