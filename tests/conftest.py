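import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dcekinetics import kinetic_models as km

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def acq_grid() -> km.TimeGrid:
    """The study's acquisition grid: 10 baseline + 180 dynamic frames, 2 s."""
    return km.TimeGrid.uniform(190, 2.0)


@pytest.fixture(scope="session")
def aif(acq_grid) -> km.AIFCurve:
    """Population AIF with bolus arrival at the end of the baseline."""
    return km.population_aif(acq_grid, bolus_arrival=10 * 2.0 / 60.0)


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """A rendered miniature 3-patient cohort run directory."""
    from dcekinetics import synthetic_cohort as sc

    outdir = tmp_path_factory.mktemp("cohort") / "run"
    config = sc.fixture_config()
    truth = sc.generate_run(config, seed=7, outdir=outdir, render=True)
    return outdir, config, truth
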