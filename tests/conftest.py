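import numpy as np
import pytest

from goosegrowth import ModelParams, TraitSeries, evaluate, load_body_weight


@pytest.fixture(scope="session")
def shitou():
    return load_body_weight("shitou")


@pytest.fixture(scope="session")
def wuzong():
    return load_body_weight("wuzong")


@pytest.fixture
def make_noiseless_series():
    """Factory: exact weekly trajectory of a given law, weeks 0-12."""

    def _make(model, A, B, k, weeks=None):
        weeks = np.arange(13.0) if weeks is None else np.asarray(weeks, dtype=float)
        values = evaluate(model, ModelParams(A, B, k), weeks)
        return TraitSeries(breed="sim", trait="body weight", unit="g", weeks=weeks, values=values)

    return _make
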