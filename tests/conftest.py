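import numpy as np
import pytest

from vmibench import networks, traits, dynamics
from vmibench.pipeline import ExperimentConfig, run_ensemble


@pytest.fixture(scope="session")
def nested10():
    return networks.make_max_nested(10, 0.55)


@pytest.fixture(scope="session")
def traits10(nested10):
    return traits.sample_traits(nested10, np.random.default_rng(0))


@pytest.fixture(scope="session")
def sim10(nested10, traits10):
    return dynamics.simulate(traits10, nested10, 0.3,
                             rng=np.random.default_rng(1))


@pytest.fixture(scope="session")
def samples10(sim10):
    return dynamics.sample(sim10, 2.0, 200.0)


@pytest.fixture(scope="session")
def main_ensemble():
    """The headline study: 60 communities, delta = 0.3, 2-h sampling."""
    cfg = ExperimentConfig.main_text(
        master_seed=0,
        methods=("pearson", "delayed_pearson", "elsa", "sparcc"))
    return run_ensemble(cfg)


@pytest.fixture(scope="session")
def cv_sweep():
    """Dynamics-only sweep over delta for the variability calibration."""
    cfg = ExperimentConfig(deltas=(0.1, 0.3, 0.5), frequencies=(2.0,),
                           methods=(), master_seed=0)
    return run_ensemble(cfg)
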