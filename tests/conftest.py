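import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cnconcord import SimulationConfig, analyze_cohort, simulate_cohort

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """Fast cohort: enough structure for every stage, runs in < 1 s."""
    return SimulationConfig(
        n_genes=300, n_samples=120, n_planted_aug=10, n_planted_ddg=8,
        n_ref_oncogenes=8, n_ref_tsgs=5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    return analyze_cohort(small_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The standard study-condition cohort (2000 genes x 500 samples)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    return analyze_cohort(default_cohort)


@pytest.fixture
def toy_matrices():
    """3-gene x 6-sample hand-checkable expression/call pair."""
    genes = pd.Index(["GA", "GB", "GC"], name="gene")
    samples = pd.Index([f"S{i}" for i in range(1, 7)], name="sample")
    calls = pd.DataFrame(
        [[0, 0, 0, 2, -2, 1],
         [0, 0, 0, 0, 2, -2],
         [0, 0, 0, 1, 1, -1]],
        index=genes, columns=samples, dtype=float)
    expression = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 0.0, 2.5],
         [5.0, 6.0, 7.0, 6.0, 9.0, 3.0],
         [4.0, 4.0, 4.0, 4.0, 4.0, 4.0]],
        index=genes, columns=samples)
    return calls, expression
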