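import numpy as np
import pytest

from fructans.io import load_reference_ratios
from fructans.linkages import LinkageClass as L
from fructans.structures import assemble_core


@pytest.fixture
def graminan_core():
    """DP-7 branched core: terminal glucose, two 2-1 units, one branch
    residue carrying a one-unit levan chain, two terminal fructoses."""
    return assemble_core(
        {L.T_FRUF: 2, L.B21_FRUF: 2, L.B26_FRUF: 1, L.DI_FRUF: 1, L.T_GLCP: 1},
        "terminal",
    )


@pytest.fixture(scope="session")
def ratio_table():
    """Packaged six-sample glucose-normalised ratio table."""
    return load_reference_ratios()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
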