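"""Prize-collecting Steiner forest: costs, prizes, solver optimality."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from isletgrid.diffexp import fit_region_model
from isletgrid.errors import ConfigurationError, InputError, ValidationError
from isletgrid.pcsf import (
    DOWN_IN_ISLET,
    UP_IN_ISLET,
    Interactome,
    PCSFParams,
    SteinerSolution,
    build_prizes,
    classify_nodes,
    edge_cost,
    full_objective,
    solve_pcsf,
)


def make_interactome(rows):
    return Interactome(
        pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])
    )


def brute_force_optimum(inter, prizes, params):
    """Exhaustive PCSF optimum over all acyclic edge subsets.

    For each forest, prized nodes outside it either pay the exclusion
    penalty or join as singleton trees at the per-tree charge, whichever
    is cheaper.  Tractable for the <=14-edge instances used here.
    """
    beta = params.beta
    omega = params.resolved_omega(prizes[prizes > 0])
    g = inter.graph
    edges = sorted(
        (min(u, v), max(u, v), g[u][v]["cost"]) for u, v in g.edges
    )
    prize = {k: v for k, v in prizes.items() if v > 0}
    best = np.inf
    for mask in range(1 << len(edges)):
        sel = [edges[i] for i in range(len(edges)) if mask >> i & 1]
        f = nx.Graph()
        f.add_edges_from((u, v) for u, v, _ in sel)
        if len(f.edges) != len(f.nodes) - nx.number_connected_components(f):
            continue  # contains a cycle
        obj = sum(c for _, _, c in sel)
        obj += omega * nx.number_connected_components(f)
        for n, p in prize.items():
            if n not in f.nodes:
                obj += min(beta * p, omega)
        best = min(best, obj)
    return best


def random_instance(rng):
    n = int(rng.integers(4, 10))
    nodes = [f"N{i}" for i in range(n)]
    pairs = list(itertools.combinations(range(n), 2))
    m = min(int(rng.integers(n - 1, 15)), len(pairs))
    sel = rng.choice(len(pairs), size=m, replace=False)
    rows = [
        (nodes[pairs[k][0]], nodes[pairs[k][1]],
         float(rng.uniform(0.3, 0.99)))
        for k in sel
    ]
    inter = make_interactome(rows)
    n_prized = int(rng.integers(1, max(2, n // 2) + 1))
    prized = rng.choice(nodes, size=n_prized, replace=False)
    prizes = pd.Series(0.0, index=nodes)
    prizes[prized] = rng.uniform(0.2, 3.0, size=n_prized)
    return inter, prizes[prizes.index.isin(inter.graph.nodes)]


def solution_forest(solution):
    f = nx.Graph()
    f.add_nodes_from(solution.node_flags)
    f.add_edges_from((u, v) for u, v, _ in solution.edges)
    return f


class TestEdgeCost:
    def test_full_confidence_hits_the_floor(self):
        assert edge_cost(1.0) == pytest.approx(0.01)

    def test_half_confidence(self):
        assert edge_cost(0.5) == pytest.approx(0.51)

    def test_strictly_decreasing_in_confidence(self):
        costs = [edge_cost(c) for c in np.linspace(0.05, 1.0, 20)]
        assert all(a > b for a, b in zip(costs, costs[1:]))

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_out_of_range_confidence_rejected(self, bad):
        with pytest.raises(InputError):
            edge_cost(bad)


class TestInteractome:
    def test_duplicate_edges_collapse_to_max_confidence(self):
        inter = make_interactome(
            [("A", "B", 0.5), ("B", "A", 0.9)]
        )
        assert inter.graph["A"]["B"]["confidence"] == 0.9

    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError):
            make_interactome([("A", "A", 0.5)])

    def test_every_node_has_degree_at_least_one(self):
        inter = make_interactome([("A", "B", 0.5), ("B", "C", 0.7)])
        assert min(dict(inter.graph.degree).values()) >= 1


class TestBuildPrizes:
    @pytest.fixture(scope="class")
    def de_table(self, small_study, small_completed):
        study, _ = small_study
        return fit_region_model(
            small_completed, study.voxel_labels(), study.voxel_image_ids()
        )

    def test_no_significant_proteins_means_all_zero(self):
        de = pd.DataFrame(
            {"protein": ["A"], "contrast": ["islet_vs_rest"],
             "logFC": [3.0], "adj_p": [0.9]}
        )
        prizes = build_prizes(de, "islet_vs_rest", UP_IN_ISLET)
        assert (prizes == 0).all()

    def test_downregulated_prize_is_absolute_logfc(self):
        de = pd.DataFrame(
            {"protein": ["A"], "contrast": ["islet_vs_rest"],
             "logFC": [-1.5], "adj_p": [0.001]}
        )
        prizes = build_prizes(de, "islet_vs_rest", DOWN_IN_ISLET)
        assert prizes["A"] == pytest.approx(1.5)
        assert (build_prizes(de, "islet_vs_rest", UP_IN_ISLET) == 0).all()

    def test_prized_counts_match_significance_recount(self, de_table):
        """Cross-module consistency: the number of positive prizes equals
        a direct recount of signed significant proteins."""
        for direction, sign in ((UP_IN_ISLET, 1), (DOWN_IN_ISLET, -1)):
            prizes = build_prizes(de_table, "islet_vs_rest", direction)
            sub = de_table[de_table["contrast"] == "islet_vs_rest"]
            manual = (
                (sub["adj_p"] < 0.05) & (sign * sub["logFC"] > 0)
            ).sum()
            assert (prizes > 0).sum() == manual

    def test_unknown_contrast_rejected(self, de_table):
        with pytest.raises(InputError):
            build_prizes(de_table, "nope", UP_IN_ISLET)


class TestSolver:
    def test_two_prized_nodes_joined_by_cheap_edge(self):
        """Worked instance: both prizes kept, the 0.2-cost edge kept, and
        the reported objective (edges + excluded prizes) is 0.2 — matching
        exhaustive search."""
        inter = make_interactome([("A", "B", 0.81)])  # cost 0.2
        prizes = pd.Series({"A": 5.0, "B": 5.0})
        params = PCSFParams(beta=1.0)
        sol = solve_pcsf(inter, prizes, params)
        assert set(sol.node_flags) == {"A", "B"}
        assert sol.edges == [("A", "B", pytest.approx(0.2))]
        assert sol.objective == pytest.approx(0.2)
        assert full_objective(sol, prizes, params) == pytest.approx(
            brute_force_optimum(inter, prizes, params)
        )

    def test_expensive_edges_leave_a_singleton(self):
        """A prized node whose every incident edge costs more than any
        reachable prize stays alone."""
        inter = make_interactome(
            [("A", "B", 0.05), ("B", "C", 0.05)]  # cost 0.96 each
        )
        prizes = pd.Series({"A": 2.0, "B": 0.0, "C": 0.1})
        sol = solve_pcsf(inter, prizes, PCSFParams(beta=1.0, omega=0.5))
        assert sol.node_flags == {"A": "terminal"}
        assert sol.edges == []
        assert sol.n_trees == 1

    def test_no_positive_prizes_rejected(self):
        inter = make_interactome([("A", "B", 0.9)])
        with pytest.raises(InputError):
            solve_pcsf(inter, pd.Series({"A": 0.0}), PCSFParams())

    def test_absent_prized_nodes_dropped_with_warning(self):
        inter = make_interactome([("A", "B", 0.9)])
        prizes = pd.Series({"A": 1.0, "GHOST": 5.0})
        with pytest.warns(UserWarning, match="absent"):
            sol = solve_pcsf(inter, prizes, PCSFParams())
        assert sol.dropped == ["GHOST"]

    def test_random_instances_against_brute_force(self):
        """Over 100 random <=9-node instances the heuristic is within 2x
        of the exhaustive optimum and exact in >=80%; its forests are
        acyclic and every leaf is prized."""
        rng = np.random.default_rng(1)
        params = PCSFParams()
        n_exact, ratios = 0, []
        trials = 0
        while trials < 100:
            inter, prizes = random_instance(rng)
            if not (prizes > 0).any():
                continue
            trials += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = solve_pcsf(inter, prizes, params)
            h = full_objective(sol, prizes, params)
            b = brute_force_optimum(inter, prizes, params)
            ratios.append(h / b if b > 1e-12 else 1.0)
            if abs(h - b) < 1e-9:
                n_exact += 1
            f = solution_forest(sol)
            assert len(f.edges) == len(
                [n for n in f.nodes if f.degree(n) > 0]
            ) - sum(
                1 for c in nx.connected_components(f)
                if len(c) > 1
            )
            for leaf in (n for n in f.nodes if f.degree(n) == 1):
                assert prizes.get(leaf, 0) > 0
            for lone in (n for n in f.nodes if f.degree(n) == 0):
                assert prizes.get(lone, 0) > 0
            # never worse than doing nothing
            assert sol.objective <= params.beta * prizes[prizes > 0].sum() + 1e-9
        assert max(ratios) <= 2.0
        assert n_exact >= 80

    def test_prize_scaling_never_drops_prized_nodes(self):
        """Scaling all prizes up (fixed costs and omega) keeps at least as
        many prized nodes in the solution."""
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 30:
            inter, prizes = random_instance(rng)
            if (prizes > 0).sum() < 2:
                continue
            checked += 1
            omega = float(prizes[prizes > 0].median())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base = solve_pcsf(inter, prizes,
                                  PCSFParams(beta=1.0, omega=omega))
                scaled = solve_pcsf(inter, prizes * 3.0,
                                    PCSFParams(beta=1.0, omega=omega))
            assert len(scaled.terminals) >= len(base.terminals)

    def test_deterministic_given_input(self):
        rng = np.random.default_rng(3)
        inter, prizes = random_instance(rng)
        if not (prizes > 0).any():
            prizes.iloc[0] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = solve_pcsf(inter, prizes, PCSFParams())
            s2 = solve_pcsf(inter, prizes, PCSFParams())
        assert s1.node_flags == s2.node_flags
        assert s1.edges == s2.edges


class TestClassifyNodes:
    def test_all_prized_solution_has_no_steiner_nodes(self):
        inter = make_interactome([("A", "B", 0.9)])
        prizes = pd.Series({"A": 2.0, "B": 2.0})
        sol = solve_pcsf(inter, prizes, PCSFParams())
        table = classify_nodes(sol, prizes)
        assert (table["flag"] == "terminal").all()
        assert len(table) <= (prizes > 0).sum()

    def test_hidden_hub_recovered_as_steiner_node(
        self, small_study, small_interactome_edges
    ):
        """A planted hub bridging prized markers enters the solution as a
        Steiner (implicated, unmeasured) node."""
        _, truth = small_study
        inter = Interactome(small_interactome_edges)
        markers = [m for m in truth.islet_markers if m in inter.graph]
        prizes = pd.Series(2.0, index=pd.Index(markers))
        sol = solve_pcsf(inter, prizes, PCSFParams(beta=1.0))
        table = classify_nodes(sol, prizes)
        steiner = set(table.loc[table["flag"] == "steiner", "id"])
        assert any(s.startswith("HUB") for s in steiner)

    def test_terminal_count_bounded_by_prized_count(
        self, small_study, small_interactome_edges
    ):
        _, truth = small_study
        inter = Interactome(small_interactome_edges)
        prizes = pd.Series(1.0, index=pd.Index(truth.islet_markers))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_pcsf(inter, prizes, PCSFParams())
        assert len(sol.terminals) <= (prizes > 0).sum()
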