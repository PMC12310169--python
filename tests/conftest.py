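import numpy as np
import pytest

from magstim.coil import HEAD_SOLENOID, build_loop_stack


@pytest.fixture(scope="session")
def head_stack():
    """Loop stack of the 54-turn head solenoid used throughout."""
    return build_loop_stack(HEAD_SOLENOID)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sig3(x: float) -> float:
    """Round to three significant figures (for printed-value comparisons)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + 2)
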