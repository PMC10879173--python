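import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracle_scan

from thetascan import load_builtin_descriptor
from thetascan.motif_engine import parse_descriptor

#: the published drz-Mtgn-1 query sequence (DNA alphabet)
MTGN1 = "GGTAGCACACCTATGCGTTCCCGTCGCGCTACTGATTTAGACTAAATAGGT"

TOY_DESCRIPTOR = """\
# toy: one helix enclosing a constrained junction
order: s1 h1 s2 h1'
s1 1:1 G
h1 3:3 - wobble=0
s2 2:4 CNNN
catalytic: s2 0
cleavage: s1
nratio: 0.1
"""


@pytest.fixture(scope="session")
def minimal_descriptor():
    return load_builtin_descriptor("minimal_drz")


@pytest.fixture(scope="session")
def theta_descriptor():
    return load_builtin_descriptor("theta_final")


@pytest.fixture
def toy_descriptor():
    return parse_descriptor(TOY_DESCRIPTOR, name="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_toy_descriptor(rng, allow_pseudoknot=True):
    """A small random descriptor (<=4 variable elements) for oracle tests."""
    helix_len = int(rng.integers(2, 4))
    s_min = int(rng.integers(0, 2))
    s_max = s_min + int(rng.integers(0, 3))
    cat_len = int(rng.integers(1, 3))
    wobble = int(rng.integers(0, 2))
    base = rng.choice(list("ACGT"))
    cons = base + "N" * (cat_len - 1)
    layouts = ["order: j h1 s h1'"]
    if allow_pseudoknot:
        layouts.append("order: j h1 s h1' h2 h2'")
    layout = layouts[int(rng.integers(0, len(layouts)))]
    text = [layout, f"j {cat_len}:{cat_len} {cons}",
            f"h1 {helix_len}:{helix_len} - wobble={wobble}",
            f"s {s_min}:{s_max} -"]
    if "h2" in layout:
        text.append(f"h2 2:2 - wobble={wobble}")
    text += ["catalytic: j 0", "cleavage: j", "nratio: 0.1"]
    return parse_descriptor("\n".join(text), name="random_toy")
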