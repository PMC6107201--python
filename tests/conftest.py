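import numpy as np
import pytest

from chorusim import SimulationConfig, Strategy


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_config():
    """Factory for small, fast run configs."""

    def _make(kind="best_of_n", param=3, **kw):
        strategy = Strategy(kind, param if kind != "random" else None)
        defaults = dict(n_females=5, n_males=25, pop_mean=12.0, seed=7)
        defaults.update(kw)
        return SimulationConfig(strategy=strategy, **defaults)

    return _make
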