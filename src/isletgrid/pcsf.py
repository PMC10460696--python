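"""Prize-collecting Steiner forest integration over a weighted interactome.

Differentially expressed proteins receive prizes (|log2 fold change|, up-
and down-regulated sets solved separately); interactome edges receive costs
``1 - confidence + epsilon``.  The solver seeks a forest minimizing

    sum(edge costs) + beta * sum(prizes of excluded prized proteins),

with a per-tree charge ``omega`` (the dummy-root edge cost) controlling how
many disconnected trees the solution may contain.  The heuristic is the
classic dummy-root construction: a virtual root is joined to every prized
node at cost omega, an approximate Steiner tree (metric-closure /
shortest-path merging) connects the root and all prized nodes, the root is
removed to split the result into candidate trees, and each tree is strongly
pruned — any subtree whose connection cost exceeds the prize it captures is
discarded, so every leaf of the returned forest is a prized node.  Trees
whose net worth does not beat the per-tree charge are dropped.  The result
distinguishes terminal (prized, measured) nodes from Steiner nodes
implicated purely to connect them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

_ROOT = "__root__"

#: Direction tags for prize assignments.
UP_IN_ISLET = "up_in_islet"
DOWN_IN_ISLET = "down_in_islet"


def edge_cost(confidence: float, epsilon: float = 0.01) -> float:
    """Map an interaction confidence in (0, 1] to a positive edge cost.

    ``cost = 1 - confidence + epsilon``: strictly decreasing in confidence
    with a small positive floor at full confidence.
    """
    c = float(confidence)
    if not 0.0 < c <= 1.0:
        raise InputError(f"confidence {c} outside (0, 1]")
    if epsilon <= 0:
        raise ConfigurationError(f"epsilon must be positive, got {epsilon}")
    return 1.0 - c + epsilon


class Interactome:
    """Simple undirected confidence-weighted protein interaction graph.

    Self-loops are rejected; duplicate edges collapse to the maximum
    confidence.  Every node therefore has degree >= 1.
    """

    def __init__(self, edges: pd.DataFrame, epsilon: float = 0.01):
        required = {"protein_a", "protein_b", "confidence"}
        if not required.issubset(edges.columns):
            raise ValidationError(
                f"edge list needs columns {sorted(required)}, "
                f"got {list(edges.columns)}"
            )
        self.epsilon = epsilon
        g = nx.Graph()
        for a, b, conf in edges[["protein_a", "protein_b", "confidence"]].itertuples(
            index=False
        ):
            a, b = str(a), str(b)
            conf = float(conf)
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            if not 0.0 < conf <= 1.0:
                raise ValidationError(
                    f"confidence {conf} on edge ({a}, {b}) outside (0, 1]"
                )
            if g.has_edge(a, b):
                conf = max(conf, g[a][b]["confidence"])
            g.add_edge(a, b, confidence=conf, cost=edge_cost(conf, epsilon))
        self.graph = g

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass(frozen=True)
class PCSFParams:
    """Solver hyperparameters.

    ``beta`` scales prizes against edge costs; ``omega`` is the dummy-root
    edge cost charged once per tree (default: beta times the median
    positive prize); ``epsilon`` is the edge-cost floor.
    """

    beta: float = 1.0
    omega: float | None = None
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ConfigurationError(f"beta must be positive, got {self.beta}")
        if self.omega is not None and self.omega <= 0:
            raise ConfigurationError(f"omega must be positive, got {self.omega}")

    def resolved_omega(self, prizes: pd.Series) -> float:
        if self.omega is not None:
            return self.omega
        positive = prizes[prizes > 0]
        return float(self.beta * positive.median())


@dataclass
class SteinerSolution:
    """A forest over the interactome with terminal/Steiner node flags."""

    node_flags: dict[str, str]  # node -> "terminal" | "steiner"
    edges: list[tuple[str, str, float]]  # (u, v, cost)
    objective: float  # edge costs + beta * excluded prizes
    n_trees: int
    excluded: list[str] = field(default_factory=list)  # prized nodes left out
    dropped: list[str] = field(default_factory=list)  # prized, absent from graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_flags)

    @property
    def terminals(self) -> list[str]:
        return sorted(n for n, f in self.node_flags.items() if f == "terminal")

    @property
    def steiner_nodes(self) -> list[str]:
        return sorted(n for n, f in self.node_flags.items() if f == "steiner")


def build_prizes(
    de_table: pd.DataFrame,
    contrast: str,
    direction: str = UP_IN_ISLET,
    threshold: float = 0.05,
) -> pd.Series:
    """Prize = |logFC| for proteins significant with the requested sign.

    ``direction`` selects up- (logFC > 0) or down-regulated (logFC < 0)
    proteins of the given contrast; everything else gets prize 0, so the
    up and down networks are solved from separate assignments.
    """
    if contrast not in set(de_table["contrast"]):
        raise InputError(
            f"unknown contrast {contrast!r}; table has "
            f"{sorted(set(de_table['contrast']))}"
        )
    if direction not in (UP_IN_ISLET, DOWN_IN_ISLET):
        raise InputError(f"direction must be {UP_IN_ISLET!r} or {DOWN_IN_ISLET!r}")
    sub = de_table[de_table["contrast"] == contrast]
    sign = 1.0 if direction == UP_IN_ISLET else -1.0
    selected = (sub["adj_p"] < threshold) & (sign * sub["logFC"] > 0)
    prizes = pd.Series(0.0, index=pd.Index(sub["protein"], name="protein"))
    prizes[sub.loc[selected, "protein"]] = sub.loc[selected, "logFC"].abs().to_numpy()
    prizes.name = "prize"
    return prizes


def _strong_prune(
    tree: nx.Graph, root: str, prizes: dict[str, float], beta: float
) -> tuple[set[str], list[tuple[str, str, float]], float]:
    """Bottom-up pruning: drop any subtree whose cost exceeds its prize.

    Returns the kept nodes, kept edges and the tree's net worth
    (beta * prizes kept - edge costs kept).
    """
    order = list(nx.dfs_postorder_nodes(tree, root))
    parent = {root: None}
    for u, v in nx.dfs_edges(tree, root):
        parent[v] = u
    worth = {}
    keep_children: dict[str, list[str]] = {n: [] for n in tree.nodes}
    for v in order:
        w = beta * prizes.get(v, 0.0)
        for c in tree.neighbors(v):
            if parent.get(c) == v:
                cost = tree[v][c]["cost"]
                if worth[c] > cost:
                    w += worth[c] - cost
                    keep_children[v].append(c)
        worth[v] = w
    kept_nodes = {root}
    kept_edges = []
    stack = [root]
    while stack:
        v = stack.pop()
        for c in sorted(keep_children[v]):
            kept_nodes.add(c)
            kept_edges.append((v, c, tree[v][c]["cost"]))
            stack.append(c)
    return kept_nodes, kept_edges, worth[root]


def solve_pcsf(
    interactome: Interactome, prizes: pd.Series, params: PCSFParams | None = None
) -> SteinerSolution:
    """Approximately solve the prize-collecting Steiner forest problem.

    Deterministic given the input: nodes are processed in lexicographic
    order and the underlying Steiner-tree approximation (Mehlhorn's
    metric-closure construction) is run on a graph built in sorted order.
    Prized proteins absent from the interactome are dropped with a warning;
    prized nodes in components of their own come back as singleton trees
    when their prize beats the per-tree charge.
    """
    params = params or PCSFParams()
    prizes = prizes[prizes > 0].astype(float)
    dropped = sorted(set(prizes.index) - set(interactome.graph.nodes))
    if dropped:
        warnings.warn(
            f"{len(dropped)} prized protein(s) absent from the interactome "
            f"were dropped, e.g. {dropped[:5]}"
        )
    prizes = prizes[prizes.index.isin(interactome.graph.nodes)]
    if prizes.empty:
        raise InputError("no positively prized protein is in the interactome")
    beta = params.beta
    omega = params.resolved_omega(prizes)
    prize_map = prizes.to_dict()
    terminals = sorted(prize_map)
    total_prize = beta * float(prizes.sum())

    g = nx.Graph()
    for u, v in sorted(map(tuple, map(sorted, interactome.graph.edges))):
        g.add_edge(u, v, cost=interactome.graph[u][v]["cost"])
    for t in terminals:
        g.add_edge(_ROOT, t, cost=omega)

    # nodes unreachable from every terminal can never enter the solution
    reachable = nx.node_connected_component(g, _ROOT)
    g = g.subgraph(reachable).copy()

    steiner = nx.algorithms.approximation.steiner_tree(
        g, [_ROOT, *terminals], weight="cost", method="mehlhorn"
    )
    forest = nx.Graph()
    forest.add_nodes_from(n for n in steiner.nodes if n != _ROOT)
    forest.add_edges_from(
        (u, v, d) for u, v, d in steiner.edges(data=True) if _ROOT not in (u, v)
    )

    node_flags: dict[str, str] = {}
    kept_edges: list[tuple[str, str, float]] = []
    n_trees = 0
    for comp in sorted(nx.connected_components(forest), key=min):
        tree = forest.subgraph(comp)
        # the component hangs off the root by exactly one terminal
        attach = min(n for n in comp if steiner.has_edge(_ROOT, n))
        nodes, edges, worth = _strong_prune(tree, attach, prize_map, beta)
        if worth > omega:
            n_trees += 1
            kept_edges.extend(edges)
            for n in nodes:
                node_flags[n] = "terminal" if prize_map.get(n, 0) > 0 else "steiner"

    included_prize = beta * sum(prize_map.get(n, 0.0) for n in node_flags)
    edge_total = sum(c for _, _, c in kept_edges)
    objective = edge_total + (total_prize - included_prize)
    excluded = sorted(t for t in terminals if t not in node_flags)
    return SteinerSolution(
        node_flags=node_flags,
        edges=sorted((min(u, v), max(u, v), c) for u, v, c in kept_edges),
        objective=objective,
        n_trees=n_trees,
        excluded=excluded,
        dropped=dropped,
    )


def full_objective(
    solution: SteinerSolution, prizes: pd.Series, params: PCSFParams
) -> float:
    """Objective including the per-tree charge (for optimality comparisons)."""
    omega = params.resolved_omega(prizes[prizes > 0])
    return solution.objective + omega * solution.n_trees


def classify_nodes(
    solution: SteinerSolution,
    prizes: pd.Series,
    de_table: pd.DataFrame | None = None,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Node table with terminal/Steiner flags and prize / logFC annotation."""
    logfc = {}
    if de_table is not None:
        sub = de_table
        if contrast is not None:
            sub = de_table[de_table["contrast"] == contrast]
        logfc = dict(zip(sub["protein"], sub["logFC"]))
    rows = [
        {"id": n, "flag": flag, "prize": float(prizes.get(n, 0.0)),
         "logFC": logfc.get(n, np.nan)}
        for n, flag in sorted(solution.node_flags.items())
    ]
    return pd.DataFrame(rows, columns=["id", "flag", "prize", "logFC"])


def solution_graph(solution: SteinerSolution) -> nx.Graph:
    """The solution forest as a networkx graph (for GML export)."""
    g = nx.Graph()
    for n, flag in sorted(solution.node_flags.items()):
        g.add_node(n, flag=flag)
    for u, v, c in solution.edges:
        g.add_edge(u, v, cost=c)
    return g
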