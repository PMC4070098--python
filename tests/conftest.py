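import numpy as np
import pytest

from adaperm import PermutationPlan


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def small_plan():
    """A desk-scale plan for engine tests (alpha_p=0.05 design values)."""
    return PermutationPlan(m=1, alpha_e=0.05, alpha_p=0.05, c=0.1, b=1900, r=115)


@pytest.fixture
def tiny_plan():
    """Very small budget for fast structural tests."""
    return PermutationPlan(m=1, alpha_e=0.05, alpha_p=0.05, c=0.1, b=200, r=20)
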