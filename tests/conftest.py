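import numpy as np
import pytest

from selfest import ArchitectureParams, SelectionRegime


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_arch():
    """Tiny two-type architecture for hand-checkable cases."""
    return ArchitectureParams(
        L_A=2, L_R=3, mu_A=1e-3, mu_R=1e-3, s=0.05, h=0.1, s0_tilde=0.005
    )


@pytest.fixture
def source_regime(small_arch):
    return SelectionRegime.source(small_arch.s0_tilde)
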