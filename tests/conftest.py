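import numpy as np
import pytest
from hypothesis import settings

from cadtrace.synthetic_data import (default_panel, simulate_feature_tables,
                                     tracing_scenario, profiling_scenario)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tracing_run():
    """One feeding-experiment simulation (DC29 under AL/EL/NL, default panel)."""
    scenario = tracing_scenario(seed=7, p_cad=0.6, noise_cv=0.05)
    matrices, truth = simulate_feature_tables(scenario, default_panel())
    return scenario, matrices, truth


@pytest.fixture(scope="session")
def profiling_run():
    """One untargeted-profiling simulation (4 genotypes, default panel)."""
    scenario = profiling_scenario(seed=11, noise_cv=0.2)
    matrices, truth = simulate_feature_tables(scenario, default_panel())
    return scenario, matrices, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def class_vector(matrix, control="Col-0"):
    return np.array([1.0 if s.genotype != control else -1.0
                     for s in matrix.samples])
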