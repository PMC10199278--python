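import numpy as np
import pytest

from kdmimic import SimulationConfig, simulate_signature_compendium


@pytest.fixture(scope="session")
def small_compendium():
    """Three-line, 40-drug compendium with one mimic drug planted at rho=0.6."""
    cfg = SimulationConfig(
        n_genes=300,
        cell_lines=["A375", "MCF7", "PC3"],
        n_drugs=40,
        doses=[1.0, 10.0],
        times=[6.0, 24.0],
        n_kd_replicates=2,
        mimic_drugs={"mimic": 0.6},
        seed=11,
    )
    mats, meta = simulate_signature_compendium(cfg)
    return cfg, mats, meta


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
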