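import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from guidescout import DesignParameters


@pytest.fixture
def params():
    """Off-target analysis defaults with the candidate filters off."""
    return DesignParameters(find_paired_only=False, find_RE_cut_only=False)


@pytest.fixture
def compare_params():
    return DesignParameters.compare_defaults()


@pytest.fixture
def rng():
    return np.random.default_rng(20140923)
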