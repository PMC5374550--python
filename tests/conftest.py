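import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from multigraphlet.network_build import build_graph

#: the three-interaction consolidation example: complex membership plus
#: regulation one way and catalysis ordering the other
WORKED_TRIPLES = [
    ("PA", "in-complex-with", "PB"),
    ("PA", "controls-expression-of", "PB"),
    ("PB", "catalysis-precedes", "PA"),
]


@pytest.fixture
def worked_graph():
    return build_graph(WORKED_TRIPLES)


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def triangle_graph():
    return build_graph(
        [
            ("X", "interacts-with", "Y"),
            ("Y", "interacts-with", "Z"),
            ("Z", "interacts-with", "X"),
        ]
    )


@pytest.fixture
def path_graph():
    return build_graph(
        [("X", "interacts-with", "Y"), ("Y", "interacts-with", "Z")]
    )
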