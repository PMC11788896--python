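import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """One rendered 5x8 synthetic scene with ground truth (session cached)."""
    from hpfasternet import synth_seeds as ss

    pheno = ss.sample_phenotypes(3, seed=7)[1]
    return ss.render_scene(pheno, rows=5, cols=8, seed=21)


@pytest.fixture(scope="session")
def tiny_trained():
    """A short deterministic training run on separable synthetic data,
    shared by the tests that only need *a* trained model / history."""
    from hpfasternet import TrainConfig, tiny_config, train
    from hpfasternet.nets import Network
    from hpfasternet.synth_seeds import make_arrays

    data, _ = make_arrays(3, scenes_per_class=1, seed=11, rows=4, cols=6,
                          input_size=32)
    cfg = tiny_config("hpfasternet", num_classes=3, input_size=32)
    net = Network(cfg, seed=11)
    res = train(net, data, TrainConfig(epochs=3, batch_size=16, seed=11))
    return net, res, data
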