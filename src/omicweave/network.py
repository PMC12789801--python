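"""Prize-collecting Steiner forest extraction over an interaction network.

Significant integrated genes carry node prizes |S|; every edge costs
c(e) = 1 - confidence (clamped away from zero).  The solver selects a
forest maximising sum of collected prizes minus lambda-scaled edge costs,
with at most one tree per connected component of the base network: within
one component all selected nodes must be joined into a single tree, a
singleton prized node being the degenerate case.  An optional hub penalty
mu reduces each raw prize by mu times the node's degree in the filtered
base network (floored at zero), discouraging high-degree hubs.

`solve_pcsf` is exact (exhaustive over connected induced subsets with MST
edge sets) on components up to ``exact_max_nodes`` and falls back to a
deterministic Prim-style terminal-merging heuristic with leaf pruning on
larger components.  `brute_force_pcsf` exposes the exact enumeration as an
independent oracle for small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import InputError, InteractionNetwork
from .sscore import SScoreTable, significant_genes

logger = logging.getLogger("omicweave")

__all__ = [
    "PrizeMap",
    "PCSFSolution",
    "edge_costs",
    "assign_prizes",
    "solve_pcsf",
    "brute_force_pcsf",
    "cluster_solution",
    "rank_hubs",
]

COST_EPS = 1e-6


def edge_costs(net: InteractionNetwork) -> InteractionNetwork:
    """Set c(e) = 1 - confidence, clamped to [1e-6, 1] so no edge is free."""
    for _, _, d in net.graph.edges(data=True):
        d["cost"] = float(np.clip(1.0 - d["confidence"], COST_EPS, 1.0))
    return net


@dataclass
class PrizeMap:
    """Node prizes: raw |S| for significant genes, hub-penalised effective values."""

    raw: dict[str, float]
    effective: dict[str, float]
    terminals: set[str]
    mu: float = 0.0
    sscores: dict[str, float] = field(default_factory=dict)

    def effective_prize(self, node: str) -> float:
        return self.effective.get(node, 0.0)


def assign_prizes(
    net: InteractionNetwork,
    sscores: SScoreTable,
    alpha: float = 0.05,
    mu: float = 0.0,
    all_measured: bool = False,
) -> PrizeMap:
    """Map |S|-score prizes onto network nodes.

    Terminals are significant genes (adjusted p < alpha) present in the
    network, or every measured network gene when ``all_measured`` is set.
    Effective prize = max(0, raw - mu * degree in the base network).
    Significant genes absent from the network are logged, not dropped
    silently.
    """
    if mu < 0:
        raise InputError("hub penalty mu must be >= 0")
    g = net.graph
    table = sscores.table
    genes = significant_genes(sscores, alpha) if not all_measured else [
        str(x) for x in table.index
    ]
    raw: dict[str, float] = {}
    missing = []
    for gene in genes:
        if gene in g:
            raw[gene] = abs(float(table.loc[gene, "sscore"]))
        else:
            missing.append(gene)
    if missing:
        logger.info(
            "%d prized gene(s) absent from the network: %s%s",
            len(missing), missing[:10], "..." if len(missing) > 10 else "",
        )
    if not raw:
        raise InputError(
            "no significant gene maps into the network; consider a larger alpha "
            "or a broader interaction network"
        )
    effective = {v: max(0.0, p - mu * g.degree(v)) for v, p in raw.items()}
    sscore_attr = {v: float(table.loc[v, "sscore"]) for v in raw}
    return PrizeMap(
        raw=raw,
        effective=effective,
        terminals={v for v, p in raw.items() if p > 0},
        mu=mu,
        sscores=sscore_attr,
    )


@dataclass
class PCSFSolution:
    """Extracted forest with objective value and terminal/Steiner labels."""

    graph: nx.Graph  # node attrs: prize, sscore, terminal; edge attrs: cost, confidence
    objective: float
    lam: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def terminals(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("terminal"))

    @property
    def steiner_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if not d.get("terminal"))

    def recompute_objective(self) -> float:
        prize = sum(d.get("prize", 0.0) for _, d in self.graph.nodes(data=True))
        cost = sum(d["cost"] for _, _, d in self.graph.edges(data=True))
        return prize - self.lam * cost


def _assemble_solution(
    net: InteractionNetwork, prizes: PrizeMap, lam: float,
    nodes: set[str], edges: list[tuple[str, str]], objective: float,
) -> PCSFSolution:
    g = net.graph
    out = nx.Graph()
    for v in nodes:
        out.add_node(
            v,
            prize=prizes.effective_prize(v),
            sscore=prizes.sscores.get(v, 0.0),
            terminal=v in prizes.terminals,
        )
    for u, v in edges:
        d = g[u][v]
        out.add_edge(u, v, cost=d.get("cost", 0.0), confidence=d.get("confidence", 0.0))
    return PCSFSolution(graph=out, objective=objective, lam=lam)


# ---------------------------------------------------------------------------
# exact enumeration (also the brute-force oracle)


def _best_tree_exact(
    g: nx.Graph, nodes: list[str], prize: dict[str, float], lam: float
) -> tuple[float, set[str], list[tuple[str, str]]]:
    """Best single tree (possibly empty) within one base component, exactly.

    Enumerates node subsets whose induced subgraph is connected and takes
    the minimum spanning tree of each as the cheapest edge set.
    """
    index = {v: i for i, v in enumerate(nodes)}
    edge_list = sorted(
        (lam * g[u][v].get("cost", 0.0), index[u], index[v], u, v)
        for u, v in g.edges(nodes)
        if u in index and v in index
    )
    prizes_arr = np.array([prize.get(v, 0.0) for v in nodes])
    best = (0.0, set(), [])
    n = len(nodes)
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        total_prize = float(prizes_arr[members].sum())
        if total_prize <= best[0] and len(members) > 1:
            # a tree needs >= len-1 edges each of positive cost; prizes alone
            # already cannot beat the incumbent
            continue
        # Kruskal on edges inside the mask: MST cost + connectivity check
        parent = {i: i for i in members}

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        cost = 0.0
        used = []
        n_comp = len(members)
        for w, i, j, u, v in edge_list:
            if not (mask >> i & 1 and mask >> j & 1):
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                cost += w
                used.append((u, v))
                n_comp -= 1
                if n_comp == 1:
                    break
        if n_comp != 1:
            continue  # induced subset not connected: not a single tree
        obj = total_prize - cost
        if obj > best[0] + 1e-12:
            best = (obj, {nodes[i] for i in members}, used)
    return best


def brute_force_pcsf(net: InteractionNetwork, prizes: PrizeMap, lam: float = 1.0) -> PCSFSolution:
    """Exact optimum by exhaustive enumeration; instances up to 15 nodes."""
    g = net.graph
    all_nodes = sorted(g.nodes)
    if len(all_nodes) > 15:
        raise InputError(f"brute force capped at 15 nodes, got {len(all_nodes)}")
    total_obj = 0.0
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    for comp in nx.connected_components(g):
        obj, comp_nodes, comp_edges = _best_tree_exact(
            g, sorted(comp), prizes.effective, lam
        )
        if obj > 0:
            total_obj += obj
            nodes |= comp_nodes
            edges += comp_edges
    return _assemble_solution(net, prizes, lam, nodes, edges, total_obj)


# ---------------------------------------------------------------------------
# heuristic solver


def _greedy_tree(
    g: nx.Graph, comp: list[str], prize: dict[str, float], lam: float, root: str
) -> tuple[float, set[str], list[tuple[str, str]]]:
    """Prim-style terminal merging from ``root`` followed by leaf pruning."""
    terminals = sorted((v for v in comp if prize.get(v, 0.0) > 0), key=lambda v: (-prize[v], v))
    tree = nx.Graph()
    tree.add_node(root)
    remaining = [t for t in terminals if t != root]
    while remaining:
        best_gain, best_path, best_t = 0.0, None, None
        dists, paths = nx.multi_source_dijkstra(
            g, set(tree.nodes), weight=lambda u, v, d: lam * d.get("cost", 0.0)
        )
        for t in remaining:
            if t not in dists:
                continue
            path = paths[t]
            new_nodes = [v for v in path if v not in tree]
            gain = sum(prize.get(v, 0.0) for v in new_nodes) - dists[t]
            if gain > best_gain + 1e-12 or (
                best_t is not None and abs(gain - best_gain) <= 1e-12 and t < best_t
            ):
                best_gain, best_path, best_t = gain, path, t
        if best_t is None:
            break
        for u, v in zip(best_path[:-1], best_path[1:]):
            tree.add_edge(u, v)
        remaining.remove(best_t)
    # prune: repeatedly drop leaves whose prize does not pay for their edge
    changed = True
    while changed and tree.number_of_nodes() > 1:
        changed = False
        for leaf in sorted(v for v in tree.nodes if tree.degree(v) == 1):
            if tree.number_of_nodes() == 1:
                break
            (nbr,) = tree.neighbors(leaf)
            margin = prize.get(leaf, 0.0) - lam * g[leaf][nbr].get("cost", 0.0)
            if margin < 0:
                tree.remove_node(leaf)
                changed = True
    obj = sum(prize.get(v, 0.0) for v in tree.nodes) - lam * sum(
        g[u][v].get("cost", 0.0) for u, v in tree.edges
    )
    return obj, set(tree.nodes), [tuple(sorted(e)) for e in tree.edges]


def solve_pcsf(
    net: InteractionNetwork,
    prizes: PrizeMap,
    lam: float = 1.0,
    exact_max_nodes: int = 12,
    n_starts: int = 5,
) -> PCSFSolution:
    """Extract the prize-collecting forest (one tree per base component).

    Components up to ``exact_max_nodes`` nodes are solved exactly; larger
    ones by the greedy terminal-merging heuristic restarted from the
    ``n_starts`` highest-prize terminals.  The result is always at least as
    good as the best single prized node, and deterministic for a fixed
    input ordering.
    """
    if lam <= 0:
        raise InputError("lambda must be > 0")
    g = net.graph
    if not any(p > 0 for p in prizes.effective.values()):
        logger.warning("no positive effective prize; returning an empty solution")
        return _assemble_solution(net, prizes, lam, set(), [], 0.0)
    total_obj = 0.0
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    for comp in nx.connected_components(g):
        comp_sorted = sorted(comp)
        comp_terms = [v for v in comp_sorted if prizes.effective.get(v, 0.0) > 0]
        if not comp_terms:
            continue
        if len(comp_sorted) <= exact_max_nodes:
            obj, comp_nodes, comp_edges = _best_tree_exact(
                g, comp_sorted, prizes.effective, lam
            )
        else:
            starts = sorted(comp_terms, key=lambda v: (-prizes.effective[v], v))[:n_starts]
            obj, comp_nodes, comp_edges = max(
                (_greedy_tree(g, comp_sorted, prizes.effective, lam, s) for s in starts),
                key=lambda r: r[0],
            )
            # contract guarantee: never worse than the best singleton
            best_term = max(comp_terms, key=lambda v: (prizes.effective[v], v))
            if prizes.effective[best_term] > obj:
                obj, comp_nodes, comp_edges = prizes.effective[best_term], {best_term}, []
        if obj > 0:
            total_obj += obj
            nodes |= comp_nodes
            edges += comp_edges
    return _assemble_solution(net, prizes, lam, nodes, edges, total_obj)


# ---------------------------------------------------------------------------
# downstream module analysis


def cluster_solution(sol: PCSFSolution) -> dict[str, int]:
    """Greedy modularity clustering of the solution subgraph.

    Edge weights are the interaction confidences.  Clusters are numbered by
    decreasing size (ties by smallest member name); singletons allowed.
    """
    g = sol.graph
    if g.number_of_nodes() < 2:
        raise InputError("cluster_solution needs a solution with >=2 nodes")
    if g.number_of_edges() == 0:
        comms = [{n} for n in sorted(g.nodes)]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g, weight="confidence")]
        clustered = set().union(*comms) if comms else set()
        comms += [{n} for n in sorted(set(g.nodes) - clustered)]
    comms.sort(key=lambda c: (-len(c), min(c)))
    return {node: i for i, comm in enumerate(comms) for node in sorted(comm)}


def rank_hubs(sol: PCSFSolution, top_k: int | None = None) -> pd.DataFrame:
    """Rank solution nodes by a composite degree/betweenness hub score.

    Both centralities are min-max normalised within the solution and
    averaged; ties break by prize, then node name.
    """
    g = sol.graph
    if g.number_of_nodes() < 3:
        raise InputError("rank_hubs needs a solution with >=3 nodes")
    nodes = sorted(g.nodes)
    deg = np.array([g.degree(v) for v in nodes], float)
    btw_map = nx.betweenness_centrality(g, normalized=True)
    btw = np.array([btw_map[v] for v in nodes], float)

    def minmax(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        return (x - x.min()) / span if span > 0 else np.zeros_like(x)

    score = 0.5 * (minmax(deg) + minmax(btw))
    prize = np.array([g.nodes[v].get("prize", 0.0) for v in nodes])
    table = pd.DataFrame(
        {"node": nodes, "hub_score": score, "degree": deg, "betweenness": btw, "prize": prize}
    )
    table = table.sort_values(
        by=["hub_score", "prize", "node"], ascending=[False, False, True],
        kind="mergesort", ignore_index=True,
    )
    return table.head(top_k) if top_k else table
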