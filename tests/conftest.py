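import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from setshift.schedule import build_stage_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stages_series1():
    """Natural-order series-1 stage sequence (pair k -> block k)."""
    assignment = {1: "SD/CD/CDR", 2: "ID/IDR", 3: "ED/EDR"}
    return {s.name: s for s in build_stage_sequence(1, assignment)}
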