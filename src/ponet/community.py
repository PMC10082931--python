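"""Map-equation (Infomap-style) community detection, hubs and directed
gene-linkage extraction.

The two-level map equation scores a partition M by the expected per-step
description length of a random walk coded with one index codebook over
modules and one codebook per module:

    L(M) = q * H(Q) + sum_i p_i * H(P_i)

with module exit rates q_i = cut_i / (2W) in undirected flow, module
codebook usage p_i = q_i + sum of member visit rates, and entropies in
bits. The optimiser performs seeded greedy local moves plus module-level
aggregation passes (Louvain-style) and keeps the best of several restarts;
a hierarchy is grown by recursively re-partitioning each module's induced
subnetwork while the split lowers its codelength.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError

log = logging.getLogger(__name__)

TELEPORT = 0.15  # teleportation probability for directed (PageRank) flow


def _plogp(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out if out.ndim else float(out)


def visit_rates(graph: nx.Graph, directed: bool = False) -> dict:
    """Stationary visit rate per node; rates sum to 1.

    Undirected flow: strength / (2 * total edge weight), which covers
    disconnected components weighted by their edge mass. Directed flow:
    PageRank with teleportation 0.15.
    """
    if graph.number_of_nodes() == 0 or graph.number_of_edges() == 0:
        raise DegenerateInputError("visit rates undefined on an empty network")
    if directed:
        return nx.pagerank(graph if graph.is_directed() else graph.to_directed(),
                           alpha=1 - TELEPORT, weight="weight",
                           tol=1e-13, max_iter=10000)
    w_total = graph.size(weight="weight")
    return {n: graph.degree(n, weight="weight") / (2.0 * w_total) for n in graph.nodes}


def map_equation_codelength(graph: nx.Graph, partition: dict) -> float:
    """Two-level map-equation codelength (bits) of ``partition`` on ``graph``.

    ``partition`` maps every node to a module id; relabeling modules leaves
    the codelength unchanged.
    """
    nodes = set(graph.nodes)
    if set(partition) != nodes:
        missing = nodes - set(partition)
        raise ConfigError(f"partition does not cover all nodes (missing {sorted(missing)[:5]}...)"
                          if missing else "partition has extra nodes")
    rates = visit_rates(graph)
    modules = {}
    for n, m in partition.items():
        modules.setdefault(m, []).append(n)
    w_total = graph.size(weight="weight")
    q_list, p_list, member_rates = [], [], []
    for members in modules.values():
        mset = set(members)
        cut = sum(
            d.get("weight", 1.0)
            for u, v, d in graph.edges(members, data=True)
            if (v not in mset) or (u not in mset)
        )
        q_i = cut / (2.0 * w_total)
        p_i = q_i + sum(rates[n] for n in members)
        q_list.append(q_i)
        p_list.append(p_i)
        member_rates.append([rates[n] for n in members])
    q = sum(q_list)
    # index codebook
    index_len = 0.0
    if q > 0:
        probs = np.array(q_list) / q
        index_len = q * float(-_plogp(probs).sum())
    # module codebooks
    module_len = 0.0
    for q_i, p_i, mr in zip(q_list, p_list, member_rates):
        if p_i <= 0:
            continue
        probs = np.array([q_i] + mr) / p_i
        module_len += p_i * float(-_plogp(probs).sum())
    return index_len + module_len


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class _FlowState:
    """Incremental codelength bookkeeping for greedy moves.

    Uses the expanded form
    L = plogp(q) - 2*sum_i plogp(q_i) + sum_i plogp(p_i) - sum_a plogp(p_a),
    where only module-level terms change under a node move.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.nodes = list(graph.nodes)
        self.rates = visit_rates(graph)
        self.w_total = graph.size(weight="weight")
        self.node_const = -float(_plogp(np.array([self.rates[n] for n in self.nodes])).sum())
        self.module_of = {n: i for i, n in enumerate(self.nodes)}
        # external (non-self-loop) flow per node: self-loops never cross a cut
        self.ext_flow = {}
        for n in self.nodes:
            self_w = graph[n][n].get("weight", 1.0) if graph.has_edge(n, n) else 0.0
            deg = graph.degree(n, weight="weight")
            self.ext_flow[n] = (deg - 2.0 * self_w) / (2.0 * self.w_total)
        self.mod_rate = {}
        self.mod_cut = {}
        for i, n in enumerate(self.nodes):
            self.mod_rate[i] = self.rates[n]
            self.mod_cut[i] = self.ext_flow[n]
        # running sums for O(1) codelength evaluation
        self.sum_q = sum(self.mod_cut.values())
        self.sum_plogp_q = sum(float(_plogp(v)) for v in self.mod_cut.values())
        self.sum_plogp_p = sum(
            float(_plogp(self.mod_cut[m] + self.mod_rate[m])) for m in self.mod_cut
        )

    def codelength(self) -> float:
        val = float(_plogp(self.sum_q)) if self.sum_q > 0 else 0.0
        return val - 2.0 * self.sum_plogp_q + self.sum_plogp_p + self.node_const

    def _links_to_modules(self, node):
        out = {}
        for _, v, d in self.graph.edges(node, data=True):
            if v == node:
                continue
            out[self.module_of[v]] = out.get(self.module_of[v], 0.0) + d.get("weight", 1.0)
        return out

    def try_best_move(self, node) -> bool:
        """Greedily move ``node`` to the neighbouring module minimising L."""
        links = self._links_to_modules(node)
        cur = self.module_of[node]
        candidates = [m for m in links if m != cur]
        if not candidates:
            return False
        rate = self.rates[node]
        deg_flow = self.ext_flow[node]
        before = self.codelength()
        best, best_delta = cur, -1e-12
        for cand in candidates:
            self._apply(node, cur, cand, links, rate, deg_flow)
            delta = self.codelength() - before
            self._apply(node, cand, cur, links, rate, deg_flow)
            if delta < best_delta:
                best_delta, best = delta, cand
        if best != cur:
            self._apply(node, cur, best, links, rate, deg_flow)
            return True
        return False

    def _set_module(self, m, rate, cut):
        """Update module m's stats and the running sums."""
        old_cut = self.mod_cut.get(m, 0.0)
        old_rate = self.mod_rate.get(m, 0.0)
        self.sum_q += cut - old_cut
        self.sum_plogp_q += float(_plogp(max(cut, 0.0))) - float(_plogp(max(old_cut, 0.0)))
        self.sum_plogp_p += float(_plogp(max(cut + rate, 0.0))) - float(
            _plogp(max(old_cut + old_rate, 0.0))
        )
        self.mod_rate[m] = rate
        self.mod_cut[m] = cut

    def _apply(self, node, src, dst, links, rate, deg_flow):
        w_src = links.get(src, 0.0) / (2.0 * self.w_total)
        w_dst = links.get(dst, 0.0) / (2.0 * self.w_total)
        # leaving src: module loses the node's rate; links to src become cut,
        # the node's other edges stop contributing to src's cut
        self._set_module(src, self.mod_rate[src] - rate,
                         self.mod_cut[src] + 2.0 * w_src - deg_flow)
        self._set_module(dst, self.mod_rate.get(dst, 0.0) + rate,
                         self.mod_cut.get(dst, 0.0) + deg_flow - 2.0 * w_dst)
        self.module_of[node] = dst


def _two_level_partition(graph: nx.Graph, seed: int, n_restarts: int) -> dict:
    """Best-of-restarts greedy two-level partition (local moves + merges)."""
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(graph.nodes)}
    best_part, best_len = None, np.inf
    rng = np.random.default_rng(seed)
    single = map_equation_codelength(graph, {n: 0 for n in graph.nodes})
    for _ in range(n_restarts):
        part = _one_greedy_run(graph, rng)
        length = map_equation_codelength(graph, part)
        if length < best_len:
            best_part, best_len = part, length
    if best_len > single + 1e-12:
        best_part = {n: 0 for n in graph.nodes}
    # contiguous ids
    relabel = {}
    out = {}
    for n in graph.nodes:
        m = best_part[n]
        relabel.setdefault(m, len(relabel) + 1)
        out[n] = relabel[m]
    return out


def _one_greedy_run(graph: nx.Graph, rng) -> dict:
    state = _FlowState(graph)
    nodes = list(graph.nodes)
    improved = True
    sweeps = 0
    while improved and sweeps < 50:
        improved = False
        order = rng.permutation(len(nodes))
        for idx in order:
            if state.try_best_move(nodes[idx]):
                improved = True
        sweeps += 1
    part = dict(state.module_of)
    # aggregation pass: operate on the module graph, then project back
    for _ in range(5):
        agg = nx.Graph()
        for u, v, d in graph.edges(data=True):
            mu, mv = part[u], part[v]
            w = d.get("weight", 1.0)
            if agg.has_edge(mu, mv):
                agg[mu][mv]["weight"] += w
            else:
                agg.add_edge(mu, mv, weight=w)
        for m in set(part.values()):
            if m not in agg:
                agg.add_node(m)
        if agg.number_of_edges() == 0 or agg.number_of_nodes() < 2:
            break
        sup_state = _FlowState(agg)
        changed = False
        for m in rng.permutation(list(agg.nodes)):
            if sup_state.try_best_move(m):
                changed = True
        if not changed:
            break
        sup_part = sup_state.module_of
        part = {n: sup_part[part[n]] for n in part}
    return part


@dataclass
class ModuleHierarchy:
    """Nested map-equation partition.

    ``levels[k]`` (k = 0 for M1) maps node -> hierarchical module id, a tuple
    whose first k+1 components identify the nested path; ``codelengths[k]``
    is the two-level codelength of the flat level-(k+1) partition evaluated
    on the full network.
    """

    levels: list
    codelengths: list

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def partition(self, level: int = 1) -> dict:
        return self.levels[level - 1]

    def modules_at(self, level: int = 1) -> dict:
        out = {}
        for n, m in self.levels[level - 1].items():
            out.setdefault(m, []).append(n)
        return out

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.levels[0])
        data = {
            f"M{k+1}": [":".join(map(str, self.levels[k][n])) for n in nodes]
            for k in range(self.n_levels)
        }
        return pd.DataFrame(data, index=pd.Index(nodes, name="gene"))

    def summary(self, graph: nx.Graph, level: int = 1) -> pd.DataFrame:
        rows = []
        for m, members in sorted(self.modules_at(level).items()):
            sub = graph.subgraph(members)
            n = len(members)
            rows.append((":".join(map(str, m)), n, sub.number_of_edges(),
                         2.0 * sub.number_of_edges() / n if n else 0.0))
        return pd.DataFrame(rows, columns=["module", "size", "internal_edges", "avg_degree"])


def infomap_partition(
    graph: nx.Graph, max_levels: int = 5, seed: int = 0, n_restarts: int = 10
) -> ModuleHierarchy:
    """Hierarchical map-equation partition (levels M1..M<=max_levels).

    Level 1 is the best two-level partition of the full network; deeper
    levels recursively re-partition each module's induced subnetwork and are
    accepted only when the split lowers that subnetwork's codelength. The
    split ordering is deterministic under ``seed``.
    """
    if graph.number_of_nodes() < 2:
        raise ConfigError("partitioning requires >=2 nodes")
    top = _two_level_partition(graph, seed, n_restarts)
    levels = [{n: (m,) for n, m in top.items()}]
    for depth in range(1, max_levels):
        prev = levels[-1]
        groups = {}
        for n, mid in prev.items():
            groups.setdefault(mid, []).append(n)
        nxt = {}
        any_split = False
        for i, (mid, members) in enumerate(sorted(groups.items())):
            sub = graph.subgraph(members).copy()
            if len(members) < 4 or sub.number_of_edges() < 3:
                for n in members:
                    nxt[n] = mid + (1,)
                continue
            part = _two_level_partition(sub, seed + 7919 * depth + i, max(2, n_restarts // 2))
            if len(set(part.values())) <= 1:
                for n in members:
                    nxt[n] = mid + (1,)
                continue
            split_len = map_equation_codelength(sub, part)
            single_len = map_equation_codelength(sub, {n: 0 for n in sub.nodes})
            if split_len < single_len - 1e-12:
                any_split = True
                for n in members:
                    nxt[n] = mid + (part[n],)
            else:
                for n in members:
                    nxt[n] = mid + (1,)
        if not any_split:
            break
        levels.append(nxt)
    codelengths = []
    for lev in levels:
        codelengths.append(map_equation_codelength(graph, {n: m for n, m in lev.items()}))
    return ModuleHierarchy(levels, codelengths)


# ---------------------------------------------------------------------------
# hubs and directed gene-linkage inference
# ---------------------------------------------------------------------------

def detect_hubs(
    hierarchy: ModuleHierarchy,
    graph: nx.Graph,
    module_id,
    degree_cutoff: int = 4,
    level: int = 1,
) -> list:
    """Nodes of the module's induced subnetwork with degree >= cutoff,
    sorted by degree descending then id."""
    module_id = tuple(module_id) if not isinstance(module_id, tuple) else module_id
    members = [n for n, m in hierarchy.partition(level).items() if m[:level] == module_id[:level]]
    if not members:
        raise ConfigError(f"unknown module {module_id}")
    sub = graph.subgraph(members)
    hubs = [(n, sub.degree(n)) for n in sub.nodes if sub.degree(n) >= degree_cutoff]
    hubs.sort(key=lambda x: (-x[1], str(x[0])))
    return [n for n, _ in hubs]


def extract_gli(net, hierarchy: ModuleHierarchy | None = None, module_id=None, level: int = 1) -> pd.DataFrame:
    """Directed gene-linkage inferences from a consensus network.

    Returns one record per directed edge (source regulator -> target), with
    the module id when a hierarchy is supplied; ``module_id`` restricts the
    list to edges with both endpoints inside one module.
    """
    edges = net.edges[net.edges["directed"]]
    rows = []
    part = hierarchy.partition(level) if hierarchy is not None else {}
    want = tuple(module_id) if module_id is not None and not isinstance(module_id, tuple) else module_id
    for row in edges.itertuples(index=False):
        ms = part.get(row.source)
        mt = part.get(row.target)
        mod = ms if ms is not None and ms == mt else None
        if want is not None and mod != want:
            continue
        rows.append(
            (row.source, row.target,
             ":".join(map(str, mod)) if mod else "",
             row.score, row.methods)
        )
    return pd.DataFrame(rows, columns=["source", "target", "module", "score", "methods"])
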