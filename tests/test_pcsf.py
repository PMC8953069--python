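"""PCSF solvers: effective prizes, exact enumeration, heuristic, tuner."""

import math

import networkx as nx
import numpy as np
import pytest

import prizeforest as pf
from prizeforest.errors import SizeGuardError, TuningFailedError
from prizeforest.pcsf import PCSTParams, forest_stats, solve_exact, solve_heuristic, tune
from prizeforest.simulate import random_pcsf_instance


def graph_from(edges):
    g = nx.Graph()
    for u, v, cost in edges:
        g.add_edge(u, v, confidence=10.0**-cost, cost=cost)
    return g


class TestAdjustedPrize:
    def test_no_hub_penalty(self):
        g = graph_from([("a", "b", 0.1), ("a", "c", 0.1)])
        p = pf.adjusted_prize("a", {"a": 1.0}, g, PCSTParams(beta=2.0, mu=0.0))
        assert p == 2.0

    def test_clamped_at_zero(self):
        g = nx.star_graph(30)
        nx.set_edge_attributes(g, 0.1, "cost")
        p = pf.adjusted_prize(0, {0: 1.0}, g, PCSTParams(beta=1.0, mu=0.05))
        assert p == 0.0  # 1 - 0.05*30 = -0.5, clamped

    def test_non_terminal_is_zero_for_all_params(self):
        g = graph_from([("a", "b", 0.1)])
        for mu in (0.0, 0.01, 1.0):
            assert pf.adjusted_prize("b", {"a": 5.0}, g,
                                     PCSTParams(beta=3.0, mu=mu)) == 0.0


class TestSolveExact:
    def test_single_cheap_terminal_stays_out(self):
        # p' = 0.5 < omega = 1: excluding the node (penalty 0.5) beats a
        # singleton tree (charge 1.0)
        g = nx.Graph()
        g.add_node("a")
        sol = solve_exact(g, {"a": 0.5}, PCSTParams(omega=1.0))
        assert sol.is_empty and sol.objective == pytest.approx(0.5)

    def test_single_rich_terminal_forms_singleton_tree(self):
        g = nx.Graph()
        g.add_node("a")
        sol = solve_exact(g, {"a": 2.0}, PCSTParams(omega=1.0))
        assert set(sol.nodes) == {"a"} and sol.objective == pytest.approx(1.0)

    def test_path_collects_both_prizes_through_steiner(self):
        g = graph_from([("A", "B", 0.1), ("B", "C", 0.1)])
        sol = solve_exact(g, {"A": 5.0, "C": 5.0}, PCSTParams(omega=1.0))
        assert set(sol.nodes) == {"A", "B", "C"}
        assert sol.objective == pytest.approx(1.2)
        assert sol.steiner == {"B"}

    def test_all_prizes_zero_gives_empty_forest(self):
        g = graph_from([("A", "B", 0.1)])
        sol = solve_exact(g, {}, PCSTParams())
        assert sol.is_empty and sol.objective == 0.0

    def test_size_guard(self):
        g = nx.path_graph(25)
        nx.set_edge_attributes(g, 0.1, "cost")
        with pytest.raises(SizeGuardError):
            solve_exact(g, {0: 1.0}, PCSTParams())

    def test_omega_monotone_in_tree_count(self):
        # increasing the per-tree charge never increases the optimal number
        # of trees
        rng = np.random.default_rng(10)
        for _ in range(15):
            g, prizes, params = random_pcsf_instance(rng, max_nodes=9)
            kappas = [
                solve_exact(g, prizes, PCSTParams(om, params.beta, params.mu)).n_trees
                for om in (0.1, 0.5, 1.5, 5.0)
            ]
            assert all(a >= b for a, b in zip(kappas, kappas[1:]))

    def test_beta_monotone_in_terminals_captured(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            g, prizes, params = random_pcsf_instance(rng, max_nodes=9)
            counts = [
                len(solve_exact(g, prizes, PCSTParams(params.omega, b, params.mu)).terminals)
                for b in (0.3, 1.0, 3.0, 10.0)
            ]
            assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestSolveHeuristic:
    def test_never_beats_exact_and_usually_matches(self):
        rng = np.random.default_rng(1)
        equal = 0
        for _ in range(40):
            g, prizes, params = random_pcsf_instance(rng)
            ex = solve_exact(g, prizes, params)
            he = solve_heuristic(g, prizes, params)
            assert he.objective >= ex.objective - 1e-9
            if he.objective <= ex.objective + 1e-9:
                equal += 1
        assert equal >= 32  # 80%

    def test_objective_recomputes_from_parts(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g, prizes, params = random_pcsf_instance(rng)
            sol = solve_heuristic(g, prizes, params)
            aprz = pf.adjusted_prizes(g, prizes, params)
            excluded = sum(p for v, p in aprz.items() if v not in sol.nodes)
            cost = sum(g[u][v]["cost"] for u, v in sol.edges)
            assert sol.objective == pytest.approx(
                excluded + cost + params.omega * sol.n_trees, abs=1e-9
            )

    def test_unaffordable_omega_gives_empty_forest(self):
        g = graph_from([("A", "B", 0.1)])
        sol = solve_heuristic(g, {"A": 5.0, "B": 5.0}, PCSTParams(omega=1e6))
        assert sol.is_empty

    def test_planted_module_recovery(self, planted_interactome):
        net, module, prized = planted_interactome
        prizes = {g: 3.0 for g in prized}
        sol = solve_heuristic(net, prizes, PCSTParams(omega=1.0, beta=1.0, mu=0.01))
        recovered = [g for g in prized if g in sol.nodes]
        assert len(recovered) >= 0.8 * len(prized)
        assert any(g in sol.steiner for g in module)

    def test_forest_is_acyclic_with_terminals_per_tree(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g, prizes, params = random_pcsf_instance(rng)
            sol = solve_heuristic(g, prizes, params)
            sub = sol.subgraph()
            assert sol.is_empty or nx.is_forest(sub)
            for comp in nx.connected_components(sub):
                assert any(v in sol.terminals for v in comp)


class TestTune:
    def two_point_instance(self):
        # A - M - B: at omega=0.3 two singleton trees (mean degree 0) win;
        # at omega=1.0 the merged path (mean degree 4/3) wins
        g = graph_from([("A", "M", 0.2), ("M", "B", 0.2)])
        prizes = {"A": 2.0, "B": 2.0}
        return g, prizes

    def test_single_point_grid_selected_if_admissible(self):
        g, prizes = self.two_point_instance()
        res = tune(g, prizes, omega_values=(1.0,), beta_values=(1.0,), mu_values=(0.0,))
        assert res.best_params == PCSTParams(1.0, 1.0, 0.0)

    def test_minimum_mean_degree_wins(self):
        g, prizes = self.two_point_instance()
        lo = solve_heuristic(g, prizes, PCSTParams(0.3, 1.0, 0.0))
        hi = solve_heuristic(g, prizes, PCSTParams(1.0, 1.0, 0.0))
        assert lo.n_trees == 2 and lo.mean_degree == 0.0
        assert hi.n_trees == 1 and hi.mean_degree == pytest.approx(4 / 3)
        res = tune(g, prizes, omega_values=(0.3, 1.0), beta_values=(1.0,),
                   mu_values=(0.0,))
        assert res.best_params.omega == 0.3
        assert res.best_solution.mean_degree == 0.0
        assert len(res.grid) == 2 and res.grid["admissible"].all()

    def test_all_empty_grid_fails(self):
        g, prizes = self.two_point_instance()
        with pytest.raises(TuningFailedError):
            tune(g, prizes, omega_values=(1e6,), beta_values=(1.0,), mu_values=(0.0,))


class TestForestStats:
    def test_empty_forest_all_zero(self):
        g = nx.Graph()
        g.add_node("a")
        sol = solve_exact(g, {}, PCSTParams())
        stats = forest_stats(sol)
        assert stats["n_nodes"] == stats["n_edges"] == stats["n_trees"] == 0
        assert stats["mean_degree"] == 0.0

    def test_five_node_tree(self):
        g = nx.path_graph(5)
        nx.set_edge_attributes(g, 0.01, "cost")
        sol = solve_exact(g, {0: 10.0, 4: 10.0}, PCSTParams(omega=0.5))
        stats = forest_stats(sol)
        assert stats["n_trees"] == 1
        assert stats["mean_degree"] == pytest.approx(1.6)

    def test_two_disjoint_edges(self):
        g = graph_from([("A", "B", 0.01), ("C", "D", 0.01)])
        sol = solve_exact(g, {"A": 5.0, "B": 5.0, "C": 5.0, "D": 5.0},
                          PCSTParams(omega=0.5))
        stats = forest_stats(sol)
        assert stats["n_trees"] == 2
        assert stats["mean_degree"] == pytest.approx(1.0)


class TestExport:
    def test_sif_and_node_attributes(self, tmp_path):
        g = graph_from([("A", "B", 0.1), ("B", "C", 0.1)])
        sol = solve_exact(g, {"A": 5.0, "C": 5.0}, PCSTParams(omega=1.0))
        sif = tmp_path / "f.sif"
        pf.write_sif(sol, sif)
        lines = sif.read_text().splitlines()
        assert "A\tpp\tB" in lines and "B\tpp\tC" in lines
        from prizeforest.pcsf import write_node_attributes
        import pandas as pd

        attrs = tmp_path / "nodes.tsv"
        write_node_attributes(sol, {"A": 5.0, "C": 5.0}, attrs)
        df = pd.read_csv(attrs, sep="\t")
        assert dict(zip(df["gene"], df["role"])) == {
            "A": "terminal", "B": "steiner", "C": "terminal"
        }
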