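import numpy as np
import pytest

from rddmsim.config import SimulationConfig
from rddmsim.sirna_dynamics import ProductionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(**kw):
    """A fast simulation condition for functional tests (seconds)."""
    production = kw.pop("production", None)
    if production is None:
        production = ProductionSpec(
            relationship="saturated_linear", production_level=300, saturation_point=0.15
        )
    defaults = dict(
        n_loci=200, n_generations=3, cycle_duration=600.0, production=production
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def smoke_config():
    return small_config()
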