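import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet.abundance import AbundanceTable


def make_table(counts, taxon_ids=None, sample_ids=None, genotypes=None,
               conditions=None) -> AbundanceTable:
    """Build a valid AbundanceTable around a raw count array."""
    counts = np.asarray(counts)
    D, n = counts.shape
    taxon_ids = taxon_ids or [f"t{i}" for i in range(D)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    metadata = pd.DataFrame(
        {"genotype": genotypes or ["Col-0"] * n,
         "condition": conditions or ["LP"] * n,
         "replicate": list(range(1, n + 1))},
        index=pd.Index(sample_ids, name="sample_id"))
    return AbundanceTable(
        pd.DataFrame(counts.astype(np.int64), index=taxon_ids,
                     columns=sample_ids), metadata)


def attributed_graph(edges, abundance=None) -> nx.Graph:
    """Graph with rho/sign edge attributes and abundance node weights.

    *edges* is a list of (u, v, rho); *abundance* an optional node->b map
    (default 1.0 everywhere).
    """
    g = nx.Graph()
    for u, v, r in edges:
        g.add_edge(u, v, rho=float(r), weight=abs(float(r)),
                   sign=1 if r >= 0 else -1)
    for node in g.nodes:
        g.nodes[node]["abundance"] = float(
            1.0 if abundance is None else abundance.get(node, 1.0))
    return g


@pytest.fixture
def toy_table() -> AbundanceTable:
    counts = np.array([[10, 20, 30, 40],
                       [5, 5, 5, 5],
                       [0, 0, 1, 0],
                       [100, 80, 60, 120]])
    return make_table(counts)
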