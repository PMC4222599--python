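import numpy as np
import pytest

import intrumem as im


@pytest.fixture(scope="session")
def default_study():
    """The canonical planted-effect study (35 participants, 39 networks)."""
    return im.default_study(seed=1)


@pytest.fixture(scope="session")
def no_effect_study():
    """Same conditions with every flashback effect zeroed (negative control)."""
    return im.null_study(seed=2)


@pytest.fixture(scope="session")
def loso_default(default_study):
    """Strict (per-fold ICA refit) LOSO run on the planted-effect study."""
    return im.loso_cross_validation(
        default_study, im.PipelineConfig(), seed=0, return_fold_data=True
    )


@pytest.fixture(scope="session")
def small_study():
    """A fast 4-participant study for protocol-level unit tests."""
    cfg = im.default_config(
        seed=7, n_participants=4, grid_shape=(10, 10, 5), n_scenes=8
    )
    nets = im.make_networks(cfg, n_networks=6, n_predictive=2)
    return im.simulate_study(cfg, nets)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
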