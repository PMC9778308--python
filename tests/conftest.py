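import numpy as np
import pytest

from eegfst import SynthSpec, bundled_layout, generate_trials
from eegfst.synthetic import ClassEffect


@pytest.fixture(scope="session")
def deap_layout():
    return bundled_layout("deap32_8x9")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Short trials (8 s + 3 s baseline), few trials: fast pipeline checks."""
    return SynthSpec(
        n_trials=6,
        trial_s=11.0,
        class_effects=(ClassEffect(1, "gamma", (0, 1, 2, 3), 4.0),),
        seed=99,
    )


@pytest.fixture(scope="session")
def small_trials(small_spec):
    return generate_trials(small_spec)
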