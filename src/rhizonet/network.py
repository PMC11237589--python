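"""Signed co-occurrence networks, topology, modules and node roles.

Edges are the statistically significant compositional correlations
(default p < 0.01, no |ρ| floor); modules come from greedy (fast-greedy
agglomerative) modularity optimisation on the unweighted skeleton; node
roles follow the within-module connectivity (Zi) / among-module
connectivity (Pi) scheme: peripherals, connectors, module hubs and network
hubs, with every non-peripheral flagged as a potential keystone taxon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import (greedy_modularity_communities,
                                           modularity)

from .abundance import RelativeAbundanceTable
from .sparcc import CorrelationEstimate

__all__ = ["build_network", "assign_modules", "network_stats", "zi_pi",
           "classify_roles", "NetworkStats", "ROLES"]

ROLES = ("peripheral", "connector", "module hub", "network hub")


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    average_degree: float
    clustering_coefficient: float
    modularity: float
    relative_modularity: float | None
    positive_edge_fraction: float
    n_modules: int

    def as_dict(self) -> dict:
        return {k: (None if v is None else
                    (int(v) if isinstance(v, (int, np.integer)) else float(v)))
                for k, v in self.__dict__.items()}


def build_network(est: CorrelationEstimate,
                  table: RelativeAbundanceTable,
                  p_cut: float = 0.01,
                  min_abs_rho: float = 0.0,
                  drop_isolated: bool = True) -> nx.Graph:
    """Build the signed co-occurrence graph.

    Edge (i, j) iff p_ij < *p_cut* and |ρ_ij| ≥ *min_abs_rho*; the edge
    weight is ρ_ij with its sign kept. Node attribute ``abundance`` is the
    taxon's mean relative abundance b_j. Isolated nodes are dropped by
    default (downstream Zi/Pi and cascade metrics require degree ≥ 1).
    """
    est_ids, tab_ids = set(est.taxon_ids), set(table.taxon_ids)
    if est_ids != tab_ids:
        diff = sorted(est_ids.symmetric_difference(tab_ids))
        raise ValueError(
            f"correlation estimate and abundance table disagree on taxa: "
            f"{diff[:10]}{'...' if len(diff) > 10 else ''}")
    ids = est.taxon_ids
    b = table.mean_abundance()
    rho = est.rho.to_numpy()
    pval = est.pvalue.to_numpy()

    g = nx.Graph(p_cut=p_cut, min_abs_rho=min_abs_rho)
    for t in ids:
        g.add_node(t, abundance=float(b[t]))
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = (pval[iu, ju] < p_cut) & (np.abs(rho[iu, ju]) >= min_abs_rho)
    for i, j in zip(iu[keep], ju[keep]):
        r = float(rho[i, j])
        g.add_edge(ids[i], ids[j], rho=r, weight=abs(r),
                   sign=1 if r >= 0 else -1, p=float(pval[i, j]))
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def assign_modules(g: nx.Graph) -> dict:
    """Greedy modularity communities on the unweighted, sign-ignored
    skeleton; ties in the agglomeration are broken deterministically.
    Stores and returns ``module`` node attributes (int ids, largest first).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        communities = [{n} for n in sorted(g.nodes)]
    else:
        communities = [set(c) for c in greedy_modularity_communities(g)]
    communities.sort(key=lambda c: (-len(c), min(str(x) for x in c)))
    module_of = {node: m for m, c in enumerate(communities) for node in c}
    nx.set_node_attributes(g, module_of, "module")
    return module_of


def network_stats(g: nx.Graph, n_random: int = 100,
                  seed: int | None = None,
                  swaps_per_edge: int = 100) -> NetworkStats:
    """Topological profile of the network.

    Modularity comes from greedy optimisation on the unweighted skeleton;
    relative modularity is (M − mean M_rand)/mean M_rand over *n_random*
    degree-preserving rewirings (each applying *swaps_per_edge* × edges
    double-edge swaps). Local clustering of degree-<2 nodes counts as 0.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, m = g.number_of_nodes(), g.number_of_edges()
    module_of = assign_modules(g)
    communities = _communities_from_attr(g, module_of)
    M = modularity(g, communities) if m else 0.0
    clustering = float(np.mean(list(nx.clustering(g).values())))
    signs = [d["sign"] for _, _, d in g.edges(data=True) if "sign" in d]
    pos_frac = float(np.mean([s > 0 for s in signs])) if signs else float("nan")

    rel_mod = None
    if n_random > 0 and m > 1:
        rng = np.random.default_rng(seed)
        rand_mods = []
        for _ in range(n_random):
            h = nx.Graph(g.edges())
            try:
                nx.double_edge_swap(h, nswap=swaps_per_edge * m,
                                    max_tries=swaps_per_edge * m * 10,
                                    seed=int(rng.integers(2**31)))
            except nx.NetworkXError:
                pass  # too few swappable edges; use graph as-is
            comm = greedy_modularity_communities(h)
            rand_mods.append(modularity(h, comm))
        mean_rand = float(np.mean(rand_mods))
        if mean_rand != 0:
            rel_mod = (M - mean_rand) / mean_rand

    return NetworkStats(n_nodes=n, n_edges=m,
                        average_degree=2 * m / n,
                        clustering_coefficient=clustering,
                        modularity=float(M),
                        relative_modularity=rel_mod,
                        positive_edge_fraction=pos_frac,
                        n_modules=len(communities))


def _communities_from_attr(g: nx.Graph, module_of: dict) -> list[set]:
    comm: dict[int, set] = {}
    for node, m in module_of.items():
        comm.setdefault(m, set()).add(node)
    return [comm[k] for k in sorted(comm)]


def zi_pi(g: nx.Graph) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-own-module degree against the
    within-module degrees of all nodes of its module (population SD; a zero
    SD or singleton module gives Zi = 0). Pi = 1 − Σ_s (k_is/k_i)² over
    modules s. Nodes must have degree ≥ 1 and a module assignment.
    """
    module_of = nx.get_node_attributes(g, "module")
    if len(module_of) != g.number_of_nodes():
        module_of = assign_modules(g)
    zero = [v for v, d in g.degree() if d == 0]
    if zero:
        raise ValueError(
            f"nodes with degree 0 must be dropped before Zi/Pi: {zero[:5]}")

    within = {}   # node -> within-own-module degree
    per_module_counts = {}  # node -> {module: links}
    for v in g.nodes:
        counts: dict[int, int] = {}
        for u in g.neighbors(v):
            counts[module_of[u]] = counts.get(module_of[u], 0) + 1
        per_module_counts[v] = counts
        within[v] = counts.get(module_of[v], 0)

    members: dict[int, list] = {}
    for v, m in module_of.items():
        members.setdefault(m, []).append(v)
    mu, sd = {}, {}
    for m, vs in members.items():
        ks = np.array([within[v] for v in vs], dtype=float)
        mu[m] = ks.mean()
        sd[m] = ks.std()  # population SD

    rows = {}
    for v in g.nodes:
        m = module_of[v]
        k = g.degree(v)
        zi = 0.0 if (len(members[m]) < 2 or sd[m] == 0) else (
            (within[v] - mu[m]) / sd[m])
        pi = 1.0 - sum((c / k) ** 2 for c in per_module_counts[v].values())
        rows[v] = {"degree": k, "module": m, "zi": zi, "pi": pi}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "taxon_id"
    return out


def classify_roles(topo: pd.DataFrame, zi_cut: float = 2.5,
                   pi_cut: float = 0.62,
                   boundary: str = "strict") -> pd.DataFrame:
    """Assign node roles from (Zi, Pi).

    ``boundary="strict"`` (default): hubs require Zi strictly > zi_cut and
    connectors Pi strictly > pi_cut. ``boundary="inclusive"`` moves the
    boundary points into the hub/connector classes (Zi ≥ zi_cut,
    Pi ≥ pi_cut). Every non-peripheral node is flagged as a potential
    keystone taxon. The partition is exhaustive and exclusive.
    """
    if boundary not in ("strict", "inclusive"):
        raise ValueError("boundary must be 'strict' or 'inclusive'")
    zi = topo["zi"].to_numpy(dtype=float)
    pi = topo["pi"].to_numpy(dtype=float)
    if boundary == "strict":
        high_z, high_p = zi > zi_cut, pi > pi_cut
    else:
        high_z, high_p = zi >= zi_cut, pi >= pi_cut
    role = np.where(high_z & high_p, "network hub",
                    np.where(high_z, "module hub",
                             np.where(high_p, "connector", "peripheral")))
    out = topo.copy()
    out["role"] = role
    out["keystone"] = out["role"] != "peripheral"
    return out


def write_network(g: nx.Graph, edges_path: str | Path,
                  nodes_path: str | Path | None = None,
                  graphml_path: str | Path | None = None,
                  topo: pd.DataFrame | None = None) -> None:
    """Edge-list / node-table TSV exports plus optional GraphML."""
    edges = pd.DataFrame(
        [(u, v, d.get("rho"), d.get("sign"), d.get("p"))
         for u, v, d in g.edges(data=True)],
        columns=["source", "target", "rho", "sign", "p"])
    edges.to_csv(edges_path, sep="\t", index=False, float_format="%.6g")
    if nodes_path is not None:
        node_df = pd.DataFrame.from_dict(dict(g.nodes(data=True)),
                                         orient="index")
        if topo is not None:
            node_df = node_df.drop(columns=[c for c in node_df.columns
                                            if c in topo.columns])
            node_df = node_df.join(topo, how="left")
        node_df.index.name = "taxon_id"
        node_df.to_csv(nodes_path, sep="\t", float_format="%.6g")
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
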