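import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from megconn.connectivity import WeightedGraph

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# silence the per-band Nyquist warnings in desk-scale runs
logging.getLogger("megconn.preprocessing").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def graph_from_matrix(W, band="test", subject_id="g") -> WeightedGraph:
    """Wrap a symmetric zero-diagonal weight matrix for the metric functions."""
    W = np.asarray(W, dtype=float)
    return WeightedGraph(
        nodes=tuple(f"n{i}" for i in range(W.shape[0])),
        W=W, K=3, band=band, subject_id=subject_id, alpha=1.0, tp_crit=0.0,
    )


@pytest.fixture
def make_graph():
    return graph_from_matrix
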