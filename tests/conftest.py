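import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rejuvasim import ExperimentDesign, ModelParameters, wildtype_params
from rejuvasim.experiments import (run_growth_rate_experiment,
                                   run_retention_sweep, run_stress_experiment,
                                   run_wildtype_population)


@pytest.fixture(scope="session")
def wt_decline():
    return wildtype_params("decline")


@pytest.fixture(scope="session")
def wt_unlimited():
    return wildtype_params("unlimited")


@pytest.fixture(scope="session")
def small_design():
    """Reduced-scale wildtype design shared across experiment tests."""
    return ExperimentDesign(n_founders=2, seed=1, n_populations=5)


@pytest.fixture(scope="session")
def small_table(small_design):
    """One retention wildtype lineage (decline regime, 2 founders, depth 2)."""
    return run_wildtype_population(small_design, regime="decline")


@pytest.fixture(scope="session")
def sweep_df(small_design):
    """Retention sweep over both regimes and re in {0, 0.2957}."""
    return run_retention_sweep(small_design)


@pytest.fixture(scope="session")
def growth_df(small_design):
    """Cells-born-by-t=8 counts, 5 single-founder populations per arm."""
    return run_growth_rate_experiment(
        small_design.with_updates(re_values=(0.2957,)))


@pytest.fixture(scope="session")
def stress_df(small_design):
    """Stress (k1 x 1.01) vs unstressed arms, grouped by lineage position."""
    return run_stress_experiment(
        small_design.with_updates(re_values=(0.0, 0.2957), n_founders=3))
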