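"""Random-terminal significance and centrality-driven target prioritization.

The study's rationale: a gene is a credible treatment-specific target when it
sits in a reasonably central position of the treatment's optimal network but
almost never shows up when the same solver is run with randomly placed
prizes.  Randomization therefore re-solves the forest with the original
prize multiset scattered over random node sets, recording per-node appearance
frequencies; prioritization then keeps optimal-network nodes that are central
(degree, eigenvector and betweenness all above a floor), specific (random
frequency at most 0.01, i.e. at most one appearance in 100 runs), and not
hubs of the random networks (mean random degree centrality below the floor),
and ranks the survivors by eigenvector centrality.  Steiner nodes compete on
equal footing with prized genes — the most interesting targets are often
connectors never seen in the differential expression list.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .pcsf import ForestSolution, PCSTParams, _as_graph, _prize_dict, solve_heuristic

__all__ = ["randomize", "centralities", "prioritize"]


def randomize(
    interactome,
    prizes,
    params: PCSTParams,
    n: int = 100,
    seed: int = 0,
    solver=solve_heuristic,
    sampling: str = "uniform",
) -> pd.DataFrame:
    """Solve ``n`` forests with randomly placed terminals; aggregate per node.

    Each replicate samples |terminals| nodes (uniformly without replacement;
    ``sampling='degree'`` instead samples within degree bins so random
    terminals match the degree profile of the real ones), assigns them the
    original prize multiset in random order, and solves with the same
    parameters as the optimal run.  Returns a DataFrame indexed by every
    interactome node with columns:

    frequency
        fraction of the n random forests containing the node;
    random_degree_centrality
        mean normalized degree centrality of the node across the random
        forests containing it (0 if it never appeared);
    n_replicates
        n, repeated for convenience.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    g = _as_graph(interactome)
    raw = _prize_dict(prizes)
    values = np.array([raw[v] for v in sorted(raw) if v in g], dtype=float)
    k = len(values)
    all_nodes = sorted(g.nodes)
    rng = np.random.default_rng(seed)

    if sampling == "degree":
        degs = np.array([g.degree[v] for v in all_nodes])
        order = np.argsort(degs, kind="stable")
        bins = np.array_split(order, max(1, len(all_nodes) // max(k, 1)))
    elif sampling != "uniform":
        raise InputError(f"unknown sampling mode: {sampling}")

    appear = defaultdict(int)
    degsum = defaultdict(float)
    for _ in range(n):
        if k == 0:
            continue
        if sampling == "uniform":
            chosen = rng.choice(len(all_nodes), size=k, replace=False)
            nodes = [all_nodes[int(i)] for i in chosen]
        else:
            # sample one node per randomly chosen degree bin (approximate match)
            nodes = []
            used = set()
            real_degs = sorted(
                (g.degree[v] for v in raw if v in g), reverse=True
            )
            node_by_deg = sorted(all_nodes, key=lambda v: g.degree[v])
            degs_sorted = [g.degree[v] for v in node_by_deg]
            for d in real_degs:
                i = int(np.searchsorted(degs_sorted, d))
                lo, hi = max(0, i - 5), min(len(node_by_deg), i + 6)
                pool = [node_by_deg[j] for j in range(lo, hi) if node_by_deg[j] not in used]
                if not pool:
                    pool = [v for v in node_by_deg if v not in used]
                pick = pool[int(rng.integers(len(pool)))]
                used.add(pick)
                nodes.append(pick)
        perm = rng.permutation(values)
        rand_prizes = dict(zip(nodes, perm))
        sol = solver(g, rand_prizes, params)
        if sol.is_empty:
            continue
        dc = nx.degree_centrality(sol.subgraph())
        for v in sol.nodes:
            appear[v] += 1
            degsum[v] += dc[v]

    freq = np.array([appear[v] / n for v in all_nodes])
    mean_dc = np.array(
        [degsum[v] / appear[v] if appear[v] else 0.0 for v in all_nodes]
    )
    expected_dc = np.array([degsum[v] / n for v in all_nodes])
    return pd.DataFrame(
        {
            "frequency": freq,
            "random_degree_centrality": mean_dc,
            "random_degree_expectation": expected_dc,
            "n_replicates": n,
        },
        index=pd.Index(all_nodes, name="gene"),
    )


def _eigenvector_by_component(g: nx.Graph) -> dict:
    """Leading adjacency eigenvector per connected component, L2-normalized.

    Computed densely per component (forests are small and bipartite, where
    plain power iteration can oscillate); entries are made nonnegative.
    Singletons get centrality 1.
    """
    out = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            out[comp[0]] = 1.0
            continue
        a = nx.to_numpy_array(g, nodelist=comp)
        w, v = np.linalg.eigh(a)
        lead = np.abs(v[:, int(np.argmax(w))])
        lead /= np.linalg.norm(lead)
        for node, val in zip(comp, lead):
            out[node] = float(val)
    return out


def centralities(sol: ForestSolution) -> pd.DataFrame:
    """Degree, eigenvector and betweenness centralities of a solved forest.

    Degree centrality is deg/(N-1) over the forest; eigenvector centrality is
    computed per connected component (L2 norm 1); betweenness uses exact
    all-pairs shortest paths on the unweighted forest, normalized by
    2/((N-1)(N-2)).  An empty forest yields an empty table.
    """
    if sol.is_empty:
        return pd.DataFrame(
            columns=["degree_c", "eigen_c", "betweenness_c"],
            index=pd.Index([], name="gene"),
        )
    g = sol.subgraph()
    deg = nx.degree_centrality(g)
    eig = _eigenvector_by_component(g)
    btw = nx.betweenness_centrality(g, normalized=g.number_of_nodes() > 2)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree_c": [deg[v] for v in nodes],
            "eigen_c": [eig[v] for v in nodes],
            "betweenness_c": [btw[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def prioritize(
    centrality: pd.DataFrame,
    randomization: pd.DataFrame,
    prizes=None,
    k_per_treatment: int = 6,
    freq_max: float = 0.01,
    centrality_min: float = 0.001,
    random_degree_max: float = 0.001,
    rule: str = "methods",
    random_degree_stat: str = "expected",
    treatment: str | None = None,
) -> pd.DataFrame:
    """Apply the specificity/centrality filters and rank candidate targets.

    With the default (procedural) rule a node survives when

    * its random-terminal frequency is <= ``freq_max`` (at most one
      appearance in 100 randomized runs),
    * its degree AND eigenvector AND betweenness centralities in the optimal
      network are all > ``centrality_min``, and
    * its mean degree centrality across random networks is
      < ``random_degree_max`` (it is not a recurring random-network hub).

    Survivors are sorted by eigenvector centrality descending (ties:
    betweenness descending, then gene id) and the top ``k_per_treatment``
    are returned.  ``rule='results'`` instead drops optimal-network nodes
    with betweenness above the floor (an alternative reading that favors
    branch-end genes over mid-branch ones).

    ``random_degree_stat`` selects the random-network degree statistic the
    third filter uses: ``'expected'`` (default) averages the node's degree
    centrality over all replicates counting absences as 0, so rarely seen
    nodes score near 0 regardless of random-forest size; ``'containing'``
    averages only over the forests that contain the node.
    """
    df = centrality.join(randomization, how="left")
    for col in ("frequency", "random_degree_centrality", "random_degree_expectation"):
        if col not in df:
            df[col] = 0.0
        df[col] = df[col].fillna(0.0)
    if random_degree_stat == "expected":
        rand_deg = df["random_degree_expectation"]
    elif random_degree_stat == "containing":
        rand_deg = df["random_degree_centrality"]
    else:
        raise InputError(f"unknown random_degree_stat: {random_degree_stat}")

    keep = df["frequency"] <= freq_max
    if rule == "methods":
        keep &= (
            (df["degree_c"] > centrality_min)
            & (df["eigen_c"] > centrality_min)
            & (df["betweenness_c"] > centrality_min)
        )
    elif rule == "results":
        keep &= df["betweenness_c"] <= centrality_min
    else:
        raise InputError(f"unknown prioritization rule: {rule}")
    keep &= rand_deg < random_degree_max
    out = df[keep].copy()

    raw = {} if prizes is None else _prize_dict(prizes)
    out["prize"] = [raw.get(v, 0.0) for v in out.index]
    out["is_steiner"] = out["prize"] == 0.0
    out = out.sort_values(
        by=["eigen_c", "betweenness_c", "gene"],
        ascending=[False, False, True],
        key=lambda s: s if s.name != "gene" else s.astype(str),
    ).head(k_per_treatment)
    out = out.reset_index()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    if treatment is not None:
        out.insert(0, "treatment", treatment)
    return out
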