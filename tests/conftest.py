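import numpy as np
import pytest
from hypothesis import settings

import timesense as ts

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model1_spec():
    return ts.interval_timing_model()


@pytest.fixture(scope="session")
def model2_spec():
    return ts.when_and_how_long_model()


@pytest.fixture
def random_model(model1_spec):
    """An (untrained) interval-timing model with small random weights."""
    rng = np.random.default_rng(7)
    genomes = {
        m.name: rng.normal(0.0, 0.5, model1_spec.genome_length(m.name))
        for m in model1_spec.modules
    }
    return ts.AssembledModel(model1_spec, genomes)


@pytest.fixture
def random_session(rng):
    sched = ts.generate_schedule(rng)
    bank = ts.OscillatorBank.random(rng)
    return ts.render_session(sched, bank, rng)
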