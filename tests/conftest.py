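import numpy as np
import pytest

from mpsabbe import AngleRanges, random_conformation
from mpsabbe.tuning import Schedule


@pytest.fixture
def ranges():
    return AngleRanges()


@pytest.fixture
def yggfm_conf():
    return random_conformation("YGGFM", seed=42)


@pytest.fixture
def small_schedule():
    """A compact, hand-set schedule for fast phase tests."""
    return Schedule(
        T_initial=100.0,
        T_fMQP=10.0,
        T_fBAP=0.1,
        T_fBEAP=0.01,
        T_final=0.001,
        alpha_annealing=0.9,
        n_steps=110,
        L1=2,
        L_max=20,
        beta=1.05,
        C=3.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
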