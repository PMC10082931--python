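"""Rank standardisation, Top1 "wisdom of crowds" aggregation, directionality,
and the scale-free/transitivity threshold scan that fixes the final network.

Every method's pair scores are converted to dense descending ranks over the
same universe of unordered gene pairs (asymmetric methods contribute their
better orientation at pair level, keeping orientation-resolved ranks for the
directionality rule). Top1 keeps each pair's best rank across methods and
rescales it to a [0, 1] score, so a threshold scan over [0.9999, 1] selects
the extreme top of the aggregate ranking on any problem size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import ConfigError, DegenerateInputError
from .inference import ScoreTable

log = logging.getLogger(__name__)


@dataclass
class RankTable:
    """Dense descending ranks (1 = strongest) of one method's scores.

    ``pair_ranks`` is a Series over frozen unordered pairs (i, j) with i < j
    by gene id; for asymmetric methods ``oriented_ranks`` additionally ranks
    all ordered pairs so orientation evidence survives aggregation.
    """

    method: str
    symmetric: bool
    pair_ranks: pd.Series
    oriented_ranks: pd.Series | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ranks)


def _dense_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending competition ranks: ties share the smallest applicable rank
    and the next distinct score resumes at its positional rank, so rank/n_pairs
    stays a quantile and the [0, 1] rescale is meaningful on any problem size.

    A zero score means the method reports no dependence at all (e.g. an edge
    pruned by the data-processing inequality); such pairs are an abstention
    and take the worst rank rather than sharing a block rank.
    """
    ranks = st.rankdata(-scores, method="min").astype(int)
    ranks[scores == 0] = len(scores)
    return ranks


def standardize_ranks(table: ScoreTable) -> RankTable:
    """Descending ranks; ties share the smallest applicable rank."""
    genes = sorted(table.genes)
    if len(genes) < 2:
        raise ConfigError("need >=2 genes to rank pairs")
    m = table.scores.loc[genes, genes].to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    pair_scores = np.maximum(m[iu, ju], m[ju, iu])
    pairs = [(genes[i], genes[j]) for i, j in zip(iu, ju)]
    pair_ranks = pd.Series(_dense_ranks(pair_scores), index=pd.Index(pairs), name=table.method)
    oriented = None
    if not table.symmetric:
        io, jo = np.where(~np.eye(len(genes), dtype=bool))
        ordered = [(genes[i], genes[j]) for i, j in zip(io, jo)]
        oriented = pd.Series(
            _dense_ranks(m[io, jo]), index=pd.Index(ordered), name=table.method
        )
    return RankTable(table.method, table.symmetric, pair_ranks, oriented)


@dataclass
class ConsensusNetwork:
    """Aggregated, partially directed network over the shared gene universe.

    ``edges`` columns: source, target, score (in [0, 1]), directed (bool),
    methods (comma-joined supporters achieving the best rank). For directed
    edges source->target is the inferred orientation; undirected edges store
    source < target.
    """

    nodes: list
    edges: pd.DataFrame
    rank_tables: list = field(default_factory=list, repr=False)

    def subnetwork(self, threshold: float) -> pd.DataFrame:
        return self.edges[self.edges["score"] >= threshold]

    def to_graph(self, threshold: float = 0.0) -> nx.Graph:
        g = nx.Graph()
        sub = self.subnetwork(threshold)
        g.add_nodes_from(pd.unique(sub[["source", "target"]].to_numpy().ravel()))
        for row in sub.itertuples(index=False):
            g.add_edge(row.source, row.target, score=row.score, directed=bool(row.directed))
        return g


def aggregate_top1(rank_tables: list) -> ConsensusNetwork:
    """Top1 aggregation: each pair keeps its best rank over all methods.

    Aggregated score = 1 - (bestRank - 1) / (n_pairs - 1); supporting methods
    are those achieving the best rank; the emitted edge list is ordered by
    (best rank, second-best rank, pair id) for determinism.
    """
    if not rank_tables:
        raise ConfigError("need at least one rank table to aggregate")
    universes = [frozenset(g for p in t.pair_ranks.index for g in p) for t in rank_tables]
    if len(set(universes)) > 1:
        diff = set.union(*map(set, universes)) - set.intersection(*map(set, universes))
        raise ConfigError(f"inconsistent gene universes across methods: {sorted(diff)}")
    index = rank_tables[0].pair_ranks.index
    ranks = np.column_stack([t.pair_ranks.reindex(index).to_numpy() for t in rank_tables])
    n_pairs = len(index)
    sorted_ranks = np.sort(ranks, axis=1)
    best = sorted_ranks[:, 0]
    second = sorted_ranks[:, 1] if ranks.shape[1] > 1 else best
    score = 1.0 - (best - 1) / (n_pairs - 1) if n_pairs > 1 else np.ones_like(best, float)
    methods = [
        ",".join(t.method for t, r in zip(rank_tables, row) if r == b)
        for row, b in zip(ranks, best)
    ]
    edges = pd.DataFrame(
        {
            "source": [p[0] for p in index],
            "target": [p[1] for p in index],
            "score": score,
            "directed": False,
            "methods": methods,
            "_best": best,
            "_second": second,
        }
    )
    edges = edges.sort_values(
        ["_best", "_second", "source", "target"], kind="mergesort"
    ).drop(columns=["_best", "_second"]).reset_index(drop=True)
    nodes = sorted(set(edges["source"]) | set(edges["target"]))
    return ConsensusNetwork(nodes, edges, rank_tables)


def assign_directionality(
    net: ConsensusNetwork, asymmetric_tables: list, margin: int = 0
) -> ConsensusNetwork:
    """Orient edges on which the asymmetric evidence is unanimous.

    An edge is orientable only when at least one asymmetric method is among
    its min-rank supporters; its orientation is then decided by unanimity
    across *all* supplied asymmetric tables: it becomes A->B when every
    table ranks A->B at least ``margin + 1`` ranks better than B->A. Any
    disagreement or tie, or support by symmetric methods only, leaves the
    edge undirected.
    """
    by_name = {
        t.method: t.oriented_ranks.to_dict()
        for t in asymmetric_tables
        if t.oriented_ranks is not None
    }
    edges = net.edges.copy()
    directed = []
    src, tgt = [], []
    for row in edges.itertuples(index=False):
        a, b = row.source, row.target
        if not set(row.methods.split(",")) & set(by_name):
            directed.append(False), src.append(a), tgt.append(b)
            continue
        verdicts = set()
        for t in by_name.values():
            r_ab = t.get((a, b))
            r_ba = t.get((b, a))
            if r_ab is None or r_ba is None:
                continue
            if r_ab < r_ba - margin:
                verdicts.add("ab")
            elif r_ba < r_ab - margin:
                verdicts.add("ba")
            else:
                verdicts.add("tie")
        if verdicts == {"ab"}:
            directed.append(True), src.append(a), tgt.append(b)
        elif verdicts == {"ba"}:
            directed.append(True), src.append(b), tgt.append(a)
        else:
            directed.append(False), src.append(a), tgt.append(b)
    edges["source"], edges["target"], edges["directed"] = src, tgt, directed
    return ConsensusNetwork(net.nodes, edges, net.rank_tables)


# ---------------------------------------------------------------------------
# topology statistics and the threshold scan
# ---------------------------------------------------------------------------

def scale_free_fit(degrees) -> float:
    """R^2 of the log10(frequency) ~ log10(degree) OLS over nonzero-count bins."""
    degrees = np.asarray([d for d in degrees if d > 0], dtype=int)
    if degrees.size == 0:
        raise DegenerateInputError("no nonzero degrees")
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise DegenerateInputError(
            f"scale-free fit undefined with {len(values)} distinct degree values (<3)"
        )
    fit = st.linregress(np.log10(values), np.log10(counts))
    return float(fit.rvalue ** 2)


def transitivity(graph_or_edges) -> float:
    """Global transitivity: 3 * triangles / connected triples (undirected)."""
    if isinstance(graph_or_edges, nx.Graph):
        g = nx.Graph(graph_or_edges)
    else:
        g = nx.Graph()
        g.add_edges_from(graph_or_edges)
    if g.number_of_nodes() < 3:
        raise DegenerateInputError("transitivity requires >=3 nodes")
    return float(nx.transitivity(g))


def threshold_scan(
    net: ConsensusNetwork, lo: float = 0.9999, hi: float = 1.0, step: float = 1e-5
) -> pd.DataFrame:
    """Evaluate node/edge counts, scale-free R^2 and transitivity along a
    grid of aggregated-score thresholds (subnetworks are nested)."""
    if lo >= hi or step <= 0:
        raise ConfigError("require lo < hi and step > 0")
    rows = []
    thresholds = np.arange(lo, hi + step / 2, step)
    for t in thresholds:
        sub = net.subnetwork(t)
        g = nx.Graph()
        g.add_edges_from(zip(sub["source"], sub["target"]))
        n_nodes, n_edges = g.number_of_nodes(), g.number_of_edges()
        try:
            r2 = scale_free_fit([d for _, d in g.degree()])
        except DegenerateInputError:
            r2 = np.nan
        try:
            acc = transitivity(g)
        except DegenerateInputError:
            acc = np.nan
        rows.append((float(t), n_nodes, n_edges, r2, acc))
    return pd.DataFrame(rows, columns=["threshold", "nodes", "edges", "r2", "transitivity"])


def select_threshold(scan: pd.DataFrame, min_nodes: int = 100) -> float:
    """Threshold maximising scale-free R^2 among candidates keeping
    >= min_nodes nodes; ties resolved toward the larger network."""
    if scan.empty:
        raise ConfigError("empty threshold scan")
    ok = scan[(scan["nodes"] >= min_nodes) & scan["r2"].notna()]
    if ok.empty:
        raise ConfigError(
            f"no candidate threshold retains >= {min_nodes} nodes; widen the scan range"
        )
    best_r2 = ok["r2"].max()
    ties = ok[np.isclose(ok["r2"], best_r2)]
    row = ties.sort_values(["edges", "threshold"], ascending=[False, True]).iloc[0]
    return float(row["threshold"])
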