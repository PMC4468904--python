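import io

import numpy as np
import pytest

from metchange.io import read_reaction_table
from metchange.network import MediaSpec, apply_media, make_irreversible

#: linear chain: A_e -(uptake)-> A_c -> B_c -> C_c
TOY3_TABLE = """\
EX_A\tA_e <=> \t-1000\t1000\t
T_A\tA_e -> A_c\t0\t1000\tg1
R1\tA_c -> B_c\t0\t1000\tg2
R2\tB_c -> C_c\t0\t1000\tg3 or g4
"""

#: chain with two parallel isozyme routes for the last step
PARALLEL_TABLE = """\
EX_A\tA_e <=> \t-1000\t1000\t
T_A\tA_e -> A_c\t0\t1000\tg1
R1\tA_c -> B_c\t0\t1000\tg2
R2a\tB_c -> C_c\t0\t1000\tg3
R2b\tB_c -> C_c\t0\t1000\tg4
"""


@pytest.fixture
def toy3():
    return read_reaction_table(io.StringIO(TOY3_TABLE))


@pytest.fixture
def toy3_irrev(toy3):
    """TOY3 with media {A_e} at uptake 1, irreversibilized."""
    constrained, _ = apply_media(toy3, MediaSpec.of(["A_e"], 1.0))
    return make_irreversible(constrained)


@pytest.fixture
def parallel_net():
    net = read_reaction_table(io.StringIO(PARALLEL_TABLE))
    constrained, _ = apply_media(net, MediaSpec.of(["A_e"], 1.0))
    return make_irreversible(constrained)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
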