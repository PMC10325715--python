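import numpy as np
import pandas as pd
import pytest

import vlconn as vl


@pytest.fixture(scope="session")
def default_config() -> vl.GenerationConfig:
    return vl.GenerationConfig(seed=1)


@pytest.fixture(scope="session")
def default_connectome(default_config) -> vl.ConnectomeTable:
    return vl.generate_connectome(default_config)


@pytest.fixture(scope="session")
def default_diagram(default_connectome) -> vl.WiringDiagram:
    return vl.build_wiring_diagram(default_connectome)


@pytest.fixture()
def tiny_table() -> vl.ConnectomeTable:
    """Three neurons, hand-checkable synapse rows."""
    neurons = pd.DataFrame({"neuron_id": [1, 2, 3], "cell_type": ["SFL", "SAM", "LN"]})
    synapses = pd.DataFrame(
        {
            "pre_id": [1, 1, 1, 2],
            "post_id": [2, 2, 2, 3],
            "n_sites": [1, 2, 1, 5],
            "x_um": 0.0,
            "y_um": 0.0,
            "z_um": 0.0,
        }
    )
    return vl.ConnectomeTable(neurons=neurons, synapses=synapses)


def make_diagram(A: np.ndarray, types=None) -> vl.WiringDiagram:
    """Wiring diagram straight from an adjacency matrix (test helper)."""
    n = A.shape[0]
    return vl.WiringDiagram(
        neuron_ids=np.arange(n),
        cell_types=np.asarray(types if types is not None else ["SAM"] * n),
        A=np.asarray(A, dtype=np.int64),
    )
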