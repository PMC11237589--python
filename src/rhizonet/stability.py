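"""Community-stability metrics on co-occurrence networks.

Three complementary views of stability:

* **Robustness** — the proportion of taxa persisting after random removal
  of a fraction of nodes followed by a secondary-extinction cascade: a
  remaining node goes extinct when it has no remaining neighbours or when
  its abundance-weighted mean interaction strength (wMIS) is non-positive,
  i.e. its surviving partners no longer support it on balance.
* **Vulnerability** — each node's relative contribution to global
  efficiency (mean inverse shortest-path length over ordered pairs); the
  network's vulnerability is the maximum over nodes.
* **Cohesion** — per-sample abundance-weighted sums of each taxon's
  average positive / negative null-corrected pairwise correlations; the
  "taxa shuffle" null (independent within-taxon permutations) removes the
  correlation one expects from abundance structure alone. The
  negative:positive cohesion ratio indexes community stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import RelativeAbundanceTable

__all__ = ["weighted_interaction_strength", "simulate_robustness",
           "global_efficiency", "vulnerability", "cohesion",
           "RobustnessResult", "VulnerabilityResult", "CohesionResult"]


@dataclass
class RobustnessResult:
    removal_fraction: float
    replicates: int
    proportions: np.ndarray      # remaining/n per replicate, after cascade
    mean: float
    sd: float
    targeted: bool = False

    def as_dict(self) -> dict:
        return {"removal_fraction": self.removal_fraction,
                "replicates": self.replicates,
                "mean": self.mean, "sd": self.sd,
                "targeted": self.targeted,
                "proportions": [float(x) for x in self.proportions]}


@dataclass
class VulnerabilityResult:
    global_efficiency: float
    node_vulnerability: pd.Series    # V_i = (E − E_-i)/E
    max_vulnerability: float

    def as_dict(self) -> dict:
        return {"global_efficiency": self.global_efficiency,
                "max_vulnerability": self.max_vulnerability}


@dataclass
class CohesionResult:
    connectedness_pos: pd.Series     # c_j+ per taxon
    connectedness_neg: pd.Series     # c_j- per taxon
    cohesion: pd.DataFrame           # per sample: positive, negative, ratio
    n_null: int
    diagnostics: dict = field(default_factory=dict)


def weighted_interaction_strength(g: nx.Graph, node, remaining=None) -> float:
    """Abundance-weighted mean interaction strength of *node*.

    wMIS_i = Σ_{j∈N(i)∩remaining} b_j·ρ_ij / Σ_{j∈N(i)∩remaining} b_j,
    with b_j the neighbour's mean relative abundance; 0 when no neighbour
    remains (or all remaining neighbours have zero abundance).
    """
    if remaining is not None and node not in remaining:
        raise ValueError(f"node {node!r} not in the remaining set")
    num = den = 0.0
    for j in g.neighbors(node):
        if remaining is not None and j not in remaining:
            continue
        b = g.nodes[j].get("abundance", 1.0)
        num += b * g.edges[node, j]["rho"]
        den += b
    return num / den if den > 0 else 0.0


def _cascade(g: nx.Graph, remaining: set, rule: str) -> set:
    """Iterate secondary extinction to a fixed point."""
    remaining = set(remaining)
    changed = True
    while changed and remaining:
        changed = False
        doomed = []
        for v in remaining:
            neigh = [u for u in g.neighbors(v) if u in remaining]
            if not neigh:
                doomed.append(v)
                continue
            w = weighted_interaction_strength(g, v, remaining)
            if (w <= 0) if rule == "leq" else (w < 0):
                doomed.append(v)
        if doomed:
            remaining.difference_update(doomed)
            changed = True
    return remaining


def simulate_robustness(g: nx.Graph, removal_fraction: float = 0.5,
                        replicates: int = 100, seed: int | None = None,
                        rule: str = "leq",
                        targeted_nodes=None) -> RobustnessResult:
    """Random-removal robustness with abundance-weighted cascade.

    Per replicate, ⌊f·n⌋ uniformly chosen nodes are removed, then any node
    with no remaining neighbour or non-positive wMIS is removed iteratively
    to a fixed point; the recorded value is remaining/n. ``rule`` selects
    the extinction inequality ("leq": wMIS ≤ 0, "lt": wMIS < 0).

    ``targeted_nodes``: instead of random primary removal, delete exactly
    this node set (e.g. the keystone taxa) in every replicate; this
    targeted mode is a non-canonical extension (one replicate suffices as
    the cascade is then deterministic).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if rule not in ("leq", "lt"):
        raise ValueError("rule must be 'leq' or 'lt'")
    nodes = sorted(g.nodes)
    n = len(nodes)
    props = np.empty(replicates)
    if targeted_nodes is not None:
        targeted = set(targeted_nodes)
        remaining = _cascade(g, set(nodes) - targeted, rule)
        props[:] = len(remaining) / n
        mean = float(props.mean())
        return RobustnessResult(len(targeted) / n, replicates, props,
                                mean, float(props.std(ddof=1)) if
                                replicates > 1 else 0.0, targeted=True)
    if not 0.0 < removal_fraction < 1.0:
        raise ValueError("removal_fraction must be in (0, 1)")
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    for r in range(replicates):
        removed = rng.choice(n, size=n_remove, replace=False)
        remaining = set(nodes) - {nodes[i] for i in removed}
        remaining = _cascade(g, remaining, rule)
        props[r] = len(remaining) / n
    return RobustnessResult(removal_fraction, replicates, props,
                            float(props.mean()),
                            float(props.std(ddof=1)) if replicates > 1
                            else 0.0)


def global_efficiency(g: nx.Graph, weighted: bool = False) -> float:
    """E = mean over ordered pairs of 1/d(i,j); 1/∞ = 0 for disconnected
    pairs. Unweighted shortest paths by default; ``weighted=True`` uses
    edge length 1/|ρ| instead."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    if not weighted:
        return nx.global_efficiency(g)
    total = 0.0
    lengths = dict(nx.all_pairs_dijkstra_path_length(
        g, weight=lambda u, v, d: 1.0 / max(abs(d["rho"]), 1e-12)))
    for i in g.nodes:
        for j, dij in lengths[i].items():
            if i != j and dij > 0:
                total += 1.0 / dij
    return total / (n * (n - 1))


def vulnerability(g: nx.Graph, weighted: bool = False) -> VulnerabilityResult:
    """Per-node vulnerability V_i = (E − E_-i)/E.

    E_-i is the global efficiency of the graph with node i removed,
    normalised over the reduced node count (the node's *relative*
    contribution). Requires ≥3 nodes and E > 0.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("vulnerability needs at least 3 nodes")
    E = global_efficiency(g, weighted=weighted)
    if E == 0:
        raise ValueError("global efficiency is 0; vulnerability undefined")
    vuln = {}
    for v in g.nodes:
        h = g.copy()
        h.remove_node(v)
        E_i = global_efficiency(h, weighted=weighted)
        vuln[v] = (E - E_i) / E
    series = pd.Series(vuln, name="vulnerability")
    series.index.name = "taxon_id"
    return VulnerabilityResult(E, series, float(series.max()))


def cohesion(table: RelativeAbundanceTable, n_null: int = 200,
             seed: int | None = None) -> CohesionResult:
    """Positive and negative cohesion per sample, with a taxa-shuffle null.

    The observed Pearson correlation matrix over taxa (across samples) is
    corrected by subtracting, element-wise, its expectation under *n_null*
    datasets in which each taxon's abundances are independently permuted
    across samples. Each taxon's connectedness is the mean of the positive
    (resp. negative) corrected entries of its row; per-sample cohesion is
    the abundance-weighted sum of connectedness values, and the
    |negative|:positive ratio is reported where positive cohesion > 0.
    Constant taxa get zero correlations with a diagnostic.
    """
    X = table.fractions.to_numpy(dtype=float)   # taxa × samples
    D, n = X.shape
    if n < 3 or D < 2:
        raise ValueError("cohesion needs >= 3 samples and >= 2 taxa")

    sd = X.std(axis=1)
    constant = sd == 0
    diagnostics = {"constant_taxa": list(
        np.asarray(table.taxon_ids)[constant])}

    def _corr(M: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(M)
        C = np.nan_to_num(C, nan=0.0)
        np.fill_diagonal(C, 0.0)
        return C

    obs = _corr(X)
    rng = np.random.default_rng(seed)
    null_mean = np.zeros((D, D))
    for _ in range(n_null):
        perm = np.empty_like(X)
        for i in range(D):
            perm[i] = X[i, rng.permutation(n)]
        null_mean += _corr(perm)
    null_mean /= n_null
    corrected = obs - null_mean
    corrected[constant, :] = 0.0
    corrected[:, constant] = 0.0
    np.fill_diagonal(corrected, 0.0)

    pos_mask, neg_mask = corrected > 0, corrected < 0
    pos_cnt = pos_mask.sum(axis=1)
    neg_cnt = neg_mask.sum(axis=1)
    c_pos = np.where(pos_mask, corrected, 0.0).sum(axis=1) / np.maximum(
        pos_cnt, 1)
    c_neg = np.where(neg_mask, corrected, 0.0).sum(axis=1) / np.maximum(
        neg_cnt, 1)

    C_pos = X.T @ c_pos     # per sample
    C_neg = X.T @ c_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(C_pos > 0, np.abs(C_neg) / C_pos, np.nan)

    ids = table.taxon_ids
    coh = pd.DataFrame({"positive": C_pos, "negative": C_neg,
                        "neg_pos_ratio": ratio},
                       index=pd.Index(table.sample_ids, name="sample_id"))
    return CohesionResult(
        connectedness_pos=pd.Series(c_pos, index=ids, name="c_pos"),
        connectedness_neg=pd.Series(c_neg, index=ids, name="c_neg"),
        cohesion=coh, n_null=n_null, diagnostics=diagnostics)
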