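import warnings

import pytest

from icpattern import PipelineConfig, SimulationConfig, combat_adjust, \
    load_icg_registry, run_pipeline, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_icg_registry()


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def corrected_expr(cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr, _ = combat_adjust(cohort.expression)
    return expr


@pytest.fixture(scope="session")
def pipeline_bundle(tmp_path_factory):
    """One full default-condition pipeline run shared by end-to-end tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=7, simulate={}, n_resamples=150)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg, out)
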