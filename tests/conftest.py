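import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from percolite.rescore import TrainConfig, rescore
from percolite.simulate import SimConfig, simulate_proteome, simulate_psms
from percolite.stats import target_decoy_qvalues

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def big_sim():
    """A 200K-PSM synthetic dataset shared by the large-scale tests."""
    cfg = SimConfig(n_proteins=1000, n_spectra=100_000, seed=42)
    proteome = simulate_proteome(cfg)
    table, truth = simulate_psms(proteome, cfg)
    return cfg, proteome, table, truth


@pytest.fixture(scope="session")
def full_rescore(big_sim):
    """Full-data cross-validation rescoring of the 200K-PSM dataset."""
    _cfg, _proteome, table, _truth = big_sim
    scores, model = rescore(table, TrainConfig(seed=1))
    q = target_decoy_qvalues(scores, table.is_target)
    n_significant = int(((q <= 0.01) & table.is_target).sum())
    return scores, q, n_significant


@pytest.fixture
def small_sim():
    """A quick 10K-PSM dataset for unit-scale pipeline tests."""
    cfg = SimConfig(n_proteins=200, n_spectra=5000, seed=7)
    proteome = simulate_proteome(cfg)
    table, truth = simulate_psms(proteome, cfg)
    return cfg, proteome, table, truth
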