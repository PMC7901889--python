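import numpy as np
import pytest

from obscor.io import NodeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_nodes():
    """Three nodes, two hemispheres, easy hand-checked distances."""
    return NodeTable(
        node_ids=["L1", "L2", "R1"],
        labels=["V1", "V2", "A1"],
        hemispheres=["left", "left", "right"],
        positions=np.array([[-30.0, 0.0, 0.0],
                            [-30.0, 40.0, 0.0],
                            [30.0, 0.0, 0.0]]),
    )
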