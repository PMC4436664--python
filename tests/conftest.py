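import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helixcg.proposal_stats import SynthConfig, synthesize_stats
from helixcg.ss_graph import build_skeleton_graph, parse_dotbracket

#: two stems joined by an exterior segment, one hairpin each
TWO_HAIRPIN_DB = "((((....))))...((((....))))"

#: 50-nt three-way junction; the 4-nt middle segment is the break
JUNCTION_DB = (
    "..(((..((((("
    "...."
    ")))))...."
    "((((("
    "...."
    "))))).."
    ")))......"
)


@pytest.fixture(scope="session")
def synth_table():
    return synthesize_stats(SynthConfig(count=15), np.random.default_rng(0))


@pytest.fixture()
def two_hairpin_graph():
    return build_skeleton_graph(parse_dotbracket(TWO_HAIRPIN_DB))


@pytest.fixture()
def junction_graph():
    return build_skeleton_graph(parse_dotbracket(JUNCTION_DB))
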