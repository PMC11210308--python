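import numpy as np
import pytest
from hypothesis import settings

import lamstats as ls

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def worked_example():
    """The deterministic 60-sample miniature core."""
    return ls.generate_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_series(values, ages=None, name="x", units=""):
    values = np.asarray(values, dtype=float)
    if ages is None:
        ages = np.arange(len(values), dtype=float)
    return ls.ProxySeries(name=name, ages=ages, values=values, units=units)


@pytest.fixture()
def series_factory():
    return make_series
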