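"""Prize-Collecting Steiner Forest solvers and the mean-degree parameter tuner.

Given an interactome with edge costs, node prizes p(v) (here |logFC| of
differentially expressed genes) and parameters (omega, beta, mu), the
effective prize of a node is

    p'(v) = max(beta * p(v) - mu * deg(v), 0)

where deg(v) is the node's degree in the full interactome (the hub penalty).
A forest F (acyclic edge set whose every tree contains at least one terminal)
is scored by

    objective(F) = sum_{v not in F} p'(v) + sum_{e in F} cost(e) + omega * kappa

with kappa the number of trees.  omega therefore acts as a per-tree charge,
beta scales how many prizes are worth collecting, and mu suppresses
high-degree hubs.

Two solvers are provided: an exhaustive exact solver for small instances
(node-subset enumeration; the optimal edge set on a fixed node subset is its
minimum spanning forest) and a scalable heuristic (virtual-root shortest-path
growth followed by an MST rebuild and a strong prune).  The tuner sweeps a
parameter grid and keeps the admissible solution with minimum mean degree,
the selection rule used in the study to avoid hub-dominated "hairball"
networks.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, SizeGuardError, TuningFailedError

__all__ = [
    "PCSTParams",
    "ForestSolution",
    "TuneResult",
    "adjusted_prize",
    "adjusted_prizes",
    "solve_exact",
    "solve_heuristic",
    "tune",
    "forest_stats",
    "write_sif",
    "write_node_attributes",
]

_EPS = 1e-9


@dataclass(frozen=True)
class PCSTParams:
    """(omega, beta, mu): tree charge, prize scale, hub penalty."""

    omega: float = 1.0
    beta: float = 1.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise InputError("omega must be >= 0")
        if self.beta <= 0:
            raise InputError("beta must be > 0")
        if self.mu < 0:
            raise InputError("mu must be >= 0")


def _as_graph(interactome) -> nx.Graph:
    if isinstance(interactome, nx.Graph):
        return interactome
    return interactome.graph


def _prize_dict(prizes) -> dict:
    if isinstance(prizes, pd.Series):
        return {k: float(v) for k, v in prizes.items() if v > 0}
    return {k: float(v) for k, v in dict(prizes).items() if v > 0}


def adjusted_prize(gene, prizes, interactome, params: PCSTParams) -> float:
    """Effective prize p'(v) = max(beta * p(v) - mu * deg(v), 0) for one node."""
    g = _as_graph(interactome)
    if gene not in g:
        raise InputError(f"{gene!r} is not in the interactome")
    p = _prize_dict(prizes).get(gene, 0.0)
    if p == 0.0:
        return 0.0
    return max(params.beta * p - params.mu * g.degree[gene], 0.0)


def adjusted_prizes(interactome, prizes, params: PCSTParams) -> dict:
    """Effective prizes for every interactome node (zero-prize nodes -> 0)."""
    g = _as_graph(interactome)
    raw = _prize_dict(prizes)
    out = {}
    for v in g.nodes:
        p = raw.get(v, 0.0)
        out[v] = max(params.beta * p - params.mu * g.degree[v], 0.0) if p > 0 else 0.0
    return out


@dataclass(frozen=True)
class ForestSolution:
    """A solved forest: nodes, edges, objective and summary topology."""

    nodes: frozenset
    edges: tuple
    terminals: frozenset
    steiner: frozenset
    objective: float
    n_trees: int
    mean_degree: float
    params: PCSTParams

    @property
    def is_empty(self) -> bool:
        return not self.nodes

    def subgraph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def _objective(g: nx.Graph, aprz: dict, nodes, edges, omega: float, n_trees: int) -> float:
    excluded = sum(p for v, p in aprz.items() if v not in nodes)
    cost = sum(g[u][v]["cost"] for u, v in edges)
    return excluded + cost + omega * n_trees


def _make_solution(g, prizes, aprz, nodes, edges, params) -> ForestSolution:
    nodes = frozenset(nodes)
    edges = tuple(sorted(tuple(sorted(e)) for e in edges))
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(edges)
    if nodes and len(edges) != len(nodes) - nx.number_connected_components(sub):
        raise AssertionError("selected edges contain a cycle")
    raw = _prize_dict(prizes)
    terminals = frozenset(v for v in nodes if raw.get(v, 0.0) > 0)
    n_trees = nx.number_connected_components(sub) if nodes else 0
    for comp in nx.connected_components(sub):
        if not any(v in terminals for v in comp):
            raise AssertionError("a tree without any terminal was produced")
    mean_degree = 2.0 * len(edges) / len(nodes) if nodes else 0.0
    obj = _objective(g, aprz, nodes, edges, params.omega, n_trees)
    return ForestSolution(
        nodes=nodes,
        edges=edges,
        terminals=terminals,
        steiner=nodes - terminals,
        objective=obj,
        n_trees=n_trees,
        mean_degree=mean_degree,
        params=params,
    )


def _empty_solution(g, prizes, aprz, params) -> ForestSolution:
    return ForestSolution(
        nodes=frozenset(),
        edges=(),
        terminals=frozenset(),
        steiner=frozenset(),
        objective=sum(aprz.values()),
        n_trees=0,
        mean_degree=0.0,
        params=params,
    )


# ---------------------------------------------------------------------------
# exact solver

def _enumerate_best(nodes, edge_list, aprz, is_term, omega):
    """Best forest over subsets of ``nodes`` by exhaustive enumeration.

    ``edge_list`` holds (cost, i, j) index triples; ``aprz``/``is_term`` are
    per-index arrays.  The optimal edge set on a fixed subset is an
    omega-aware minimum spanning forest (Kruskal + union-find, adding an
    edge only while it is cheaper than the per-tree charge it saves, since
    merging two trees trades one omega for the edge cost); subsets whose
    resulting forest strands a terminal-free tree are dominated by the
    subset without those nodes and are skipped.  Returns
    (local objective, member indices, edge index pairs); the local objective
    counts excluded prizes over ``nodes`` only.  Ties break toward fewer
    nodes, then the lexicographically smallest member tuple.
    """
    n = len(nodes)
    edges = sorted(edge_list, key=lambda t: t[0])
    total_aprz = sum(aprz)
    best = None
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for mask in range(1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if members and not any(is_term[i] for i in members):
            continue
        for i in members:
            parent[i] = i
        cost = 0.0
        chosen = []
        for w, a, b in edges:
            if w >= omega:
                break  # merging costs more than the omega it saves
            if mask >> a & 1 and mask >> b & 1:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
                    cost += w
                    chosen.append((a, b))
        roots = {}
        ok = True
        for i in members:
            roots.setdefault(find(i), []).append(i)
        for comp in roots.values():
            if not any(is_term[i] for i in comp):
                ok = False
                break
        if not ok:
            continue
        kappa = len(roots)
        excluded = total_aprz - sum(aprz[i] for i in members)
        obj = excluded + cost + omega * kappa
        cand = (obj, len(members), tuple(members), chosen)
        if (
            best is None
            or obj < best[0] - _EPS
            or (abs(obj - best[0]) <= _EPS and (cand[1], cand[2]) < (best[1], best[2]))
        ):
            best = cand
    return best


def solve_exact(interactome, prizes, params: PCSTParams, max_nodes: int = 20) -> ForestSolution:
    """Globally optimal forest by exhaustive node-subset enumeration.

    For each node subset the optimal edge set is the minimum spanning forest
    of the induced subgraph; subsets with a terminal-free component are
    dominated and skipped.  Ties are broken toward fewer nodes, then the
    lexicographically smallest node set.  Guarded to ``max_nodes`` nodes.
    """
    g = _as_graph(interactome)
    n = g.number_of_nodes()
    if n > max_nodes:
        raise SizeGuardError(
            f"exact solver is limited to {max_nodes} nodes (instance has {n}); "
            "use solve_heuristic"
        )
    aprz = adjusted_prizes(g, prizes, params)
    raw = _prize_dict(prizes)
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edge_list = [(g[u][v]["cost"], idx[u], idx[v]) for u, v in g.edges()]
    best = _enumerate_best(
        nodes,
        edge_list,
        [aprz[v] for v in nodes],
        [raw.get(v, 0.0) > 0 for v in nodes],
        params.omega,
    )
    sel_nodes = {nodes[i] for i in best[2]}
    sel_edges = [(nodes[a], nodes[b]) for a, b in best[3]]
    if not sel_nodes:
        return _empty_solution(g, prizes, aprz, params)
    return _make_solution(g, prizes, aprz, sel_nodes, sel_edges, params)


# ---------------------------------------------------------------------------
# heuristic solver

_ROOT = ("__pcsf_virtual_root__",)


def _prune_subtree(tree: nx.Graph, child, parent, pruned: set) -> None:
    stack = [(child, parent)]
    while stack:
        v, par = stack.pop()
        pruned.add(v)
        for c in tree.neighbors(v):
            if c != par and c not in pruned:
                stack.append((c, v))


def _strong_prune_tree(tree: nx.Graph, root, aprz: dict) -> set:
    """Iterative post-order strong prune; returns the set of removed nodes."""
    pruned: set = set()
    value: dict = {}
    order = []
    parent = {root: None}
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for c in tree.neighbors(v):
            if c != parent[v]:
                parent[c] = v
                stack.append(c)
    for v in reversed(order):
        val = aprz.get(v, 0.0)
        for c in tree.neighbors(v):
            if parent.get(c) != v or c in pruned:
                continue
            surplus = value[c] - tree[v][c]["cost"]
            if surplus > _EPS:
                val += surplus
            else:
                _prune_subtree(tree, c, v, pruned)
        value[v] = val
    return pruned


def _finish_candidate(g, prizes, aprz, params, selected) -> ForestSolution | None:
    """Turn a candidate node set into a pruned, refined forest solution.

    Builds the MST of the induced subgraph augmented with a virtual root
    (root edges at cost omega to every selected terminal), strong-prunes it
    bottom-up (a subtree is kept only while its collected effective prizes
    exceed its connection cost), then re-optimizes each small resulting tree
    exactly over its own node set — which fixes rootings where the MST
    reached a tree through a weak terminal.  Returns None when nothing
    survives.
    """
    raw = _prize_dict(prizes)
    selected = set(selected)
    terminals = [t for t in selected if aprz.get(t, 0.0) > 0]
    if not terminals:
        return None
    aug = nx.Graph()
    aug.add_nodes_from(selected | {_ROOT})
    for u, v, d in g.edges(data=True):
        if u in selected and v in selected:
            aug.add_edge(u, v, cost=d["cost"])
    for t in terminals:
        aug.add_edge(_ROOT, t, cost=params.omega)
    # candidate sets may be disconnected from the root side; keep the root
    # component only (others carry no terminal reachable from the root)
    if not nx.is_connected(aug):
        aug = aug.subgraph(nx.node_connected_component(aug, _ROOT)).copy()
    tree = nx.minimum_spanning_tree(aug, weight="cost")

    pruned = _strong_prune_tree(tree, _ROOT, aprz)
    tree.remove_nodes_from(pruned)
    kept = set(tree.nodes) - {_ROOT}
    if not kept:
        return None
    edges = [(u, v) for u, v in tree.edges() if _ROOT not in (u, v)]

    work = nx.Graph()
    work.add_nodes_from(kept)
    work.add_edges_from(edges)
    final_nodes: set = set()
    final_edges: list = []
    for comp in nx.connected_components(work):
        comp = sorted(comp)
        if len(comp) > 14:
            final_nodes.update(comp)
            final_edges += [(u, v) for u, v in work.subgraph(comp).edges()]
            continue
        idx = {v: i for i, v in enumerate(comp)}
        sub = g.subgraph(comp)
        edge_list = [(sub[u][v]["cost"], idx[u], idx[v]) for u, v in sub.edges()]
        best = _enumerate_best(
            comp,
            edge_list,
            [aprz[v] for v in comp],
            [raw.get(v, 0.0) > 0 for v in comp],
            params.omega,
        )
        final_nodes.update(comp[i] for i in best[2])
        final_edges += [(comp[a], comp[b]) for a, b in best[3]]
    if not final_nodes:
        return None
    return _make_solution(g, prizes, aprz, final_nodes, final_edges, params)


def _growth_selection(g, terminals, params) -> set:
    """Node set reached by cheapest terminal-to-tree shortest-path growth."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, cost=d["cost"])
    for t in terminals:
        h.add_edge(_ROOT, t, cost=params.omega)
    in_tree = {_ROOT}
    remaining = set(terminals)
    while remaining:
        dist, paths = nx.multi_source_dijkstra(h, in_tree, weight="cost")
        t = min(remaining, key=lambda v: (dist.get(v, math.inf), str(v)))
        in_tree.update(paths[t])
        remaining -= in_tree
    return in_tree - {_ROOT}


def _metric_closure_selection(g, terminals) -> set:
    """Union of shortest paths along the terminal metric-closure MST."""
    selected = set(terminals)
    if len(terminals) < 2:
        return selected
    closure = nx.Graph()
    closure.add_nodes_from(terminals)
    path_of = {}
    for t in terminals:
        dist, paths = nx.single_source_dijkstra(g, t, weight="cost")
        for u in terminals:
            if u <= t or u not in dist:
                continue
            closure.add_edge(t, u, weight=dist[u])
            path_of[(t, u)] = paths[u]
    for t, u in nx.minimum_spanning_edges(closure, weight="weight", data=False):
        selected.update(path_of[(min(t, u), max(t, u))])
    return selected


def solve_heuristic(interactome, prizes, params: PCSTParams) -> ForestSolution:
    """Scalable PCSF heuristic with two constructions and a strong prune.

    A virtual root is connected to every node with positive effective prize
    at cost omega.  Two candidate node sets are built — cheapest
    terminal-to-tree shortest-path growth, and the union of shortest paths
    along the terminal metric-closure MST — and each is finished by an MST
    rebuild, a bottom-up strong prune against the root, and exact
    re-optimization of every small surviving tree.  The best-scoring
    candidate is returned; the empty forest wins if nothing beats it.
    """
    g = _as_graph(interactome)
    aprz = adjusted_prizes(g, prizes, params)
    terminals = sorted(v for v in g.nodes if aprz[v] > 0)
    empty = _empty_solution(g, prizes, aprz, params)
    if not terminals:
        return empty

    candidates = [
        _growth_selection(g, terminals, params),
        _metric_closure_selection(g, terminals),
    ]
    best = empty
    for selected in candidates:
        sol = _finish_candidate(g, prizes, aprz, params, selected)
        if sol is not None and sol.objective < best.objective - _EPS:
            best = sol
    return best


# ---------------------------------------------------------------------------
# tuner

@dataclass
class TuneResult:
    """Grid summaries plus the selected parameters and their solution."""

    grid: pd.DataFrame
    best_params: PCSTParams
    best_solution: ForestSolution


def tune(
    interactome,
    prizes,
    omega_values=(1.0, 5.0, 10.0),
    beta_values=(1.0, 5.0, 10.0, 15.0),
    mu_values=(0.01, 0.03, 0.05),
    min_terminal_frac: float = 0.1,
    solver=solve_heuristic,
) -> TuneResult:
    """Sweep (omega, beta, mu) and pick the admissible minimum-mean-degree forest.

    A grid point is admissible when its forest is nonempty and captures at
    least ``min_terminal_frac`` of the prized genes present in the
    interactome.  Ties on mean degree go to the point including more
    terminals, then smaller omega, then smaller beta, then smaller mu.
    """
    g = _as_graph(interactome)
    raw = _prize_dict(prizes)
    n_prized = sum(1 for v in raw if v in g)
    rows = []
    best = None
    if not list(itertools.product(omega_values, beta_values, mu_values)):
        raise TuningFailedError("empty tuning grid")
    for omega, beta, mu in itertools.product(omega_values, beta_values, mu_values):
        params = PCSTParams(omega=omega, beta=beta, mu=mu)
        sol = solver(interactome, prizes, params)
        n_term = len(sol.terminals)
        admissible = (not sol.is_empty) and (
            n_prized == 0 or n_term >= min_terminal_frac * n_prized
        )
        rows.append(
            {
                "omega": omega,
                "beta": beta,
                "mu": mu,
                "n_nodes": len(sol.nodes),
                "n_edges": len(sol.edges),
                "n_trees": sol.n_trees,
                "n_terminals": n_term,
                "mean_degree": sol.mean_degree,
                "objective": sol.objective,
                "admissible": admissible,
            }
        )
        if admissible:
            key = (sol.mean_degree, -n_term, omega, beta, mu)
            if best is None or key < best[0]:
                best = (key, params, sol)
    grid = pd.DataFrame(rows)
    if best is None:
        raise TuningFailedError(
            "no admissible (omega, beta, mu) grid point; grid summary:\n"
            + grid.to_string(index=False)
        )
    return TuneResult(grid=grid, best_params=best[1], best_solution=best[2])


# ---------------------------------------------------------------------------
# summaries and export

def forest_stats(sol: ForestSolution, n_prized_total: int | None = None) -> dict:
    """Counts and topology summary of a solved forest."""
    n_nodes = len(sol.nodes)
    n_terminals = len(sol.terminals)
    denom = n_prized_total if n_prized_total else n_terminals
    return {
        "n_nodes": n_nodes,
        "n_edges": len(sol.edges),
        "n_trees": sol.n_trees,
        "n_terminals": n_terminals,
        "n_steiner": len(sol.steiner),
        "mean_degree": sol.mean_degree,
        "pct_terminals_captured": (100.0 * n_terminals / denom) if denom else 0.0,
        "objective": sol.objective,
    }


def write_sif(sol: ForestSolution, path, interaction: str = "pp") -> None:
    """Write the forest in SIF format (node_a <tab> interaction <tab> node_b)."""
    with open(path, "w") as fh:
        for u, v in sorted(sol.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for v in sorted(sol.nodes):
            if all(v not in e for e in sol.edges):
                fh.write(f"{v}\n")


def write_node_attributes(sol: ForestSolution, prizes, path, logfc=None) -> None:
    """Node attribute TSV: gene, role (terminal|steiner), prize, logFC."""
    raw = _prize_dict(prizes)
    logfc = {} if logfc is None else dict(logfc)
    rows = [
        {
            "gene": v,
            "role": "terminal" if v in sol.terminals else "steiner",
            "prize": raw.get(v, 0.0),
            "logFC": logfc.get(v, float("nan")),
        }
        for v in sorted(sol.nodes)
    ]
    pd.DataFrame(rows, columns=["gene", "role", "prize", "logFC"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
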