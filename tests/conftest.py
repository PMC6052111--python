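import networkx as nx
import numpy as np
import pytest

from coexnet.expression import ExpressionMatrix
from coexnet.network import Network


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, stage_tag="raw"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        stage_tag=stage_tag,
    )


def pair_network(pairs):
    """Build a Network from an iterable of (u, v) or (u, v, score)."""
    g = nx.Graph()
    for rec in pairs:
        u, v = rec[0], rec[1]
        score = rec[2] if len(rec) > 2 else 1.0
        g.add_edge(u, v, score=score)
    return Network(graph=g)
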