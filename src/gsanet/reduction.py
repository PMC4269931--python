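"""Reduce the gene-set interaction network to the significant gene-sets.

The reduction proceeds in four steps:

1. select significant gene-sets (best p-value at or below a cutoff);
2. compute the shortest path length (SPL) between every pair of selected
   sets *on the full interaction network* -- paths may and do traverse
   non-significant intermediates, which is precisely what makes indirect
   biological connections visible;
3. draw a candidate edge between two selected sets whenever their SPL is
   strictly below the SPL cutoff;
4. optionally prune to the best (lowest-SPL) edges per node to declutter.

An SPL table is a ``dict`` keyed by ``frozenset({u, v})`` with positive
integer values; pairs that are unreachable in the network are simply absent
from the table (and never produce an edge).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .errors import UsageError
from .io_formats import Config
from .styling import (direction_score, directionality_fallback_score,
                      edge_thickness, node_size, score_to_color)

logger = logging.getLogger(__name__)

SplTable = dict[frozenset, int]
EdgeSet = dict[frozenset, int]


def filter_significant(stats: pd.DataFrame,
                       p_cutoff: float,
                       columns: list[str] | None = None) -> dict[str, float]:
    """Select gene-sets whose best p-value passes the cutoff.

    The best p-value is the minimum over the selected p-value columns,
    ignoring missing values; a set with every value missing never passes.
    The cutoff is inclusive (p_best <= p_cutoff keeps the set).

    Returns a mapping set id -> best p-value for the selected sets.
    """
    if not (0 < p_cutoff <= 1):
        raise UsageError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    if columns is not None:
        missing = [c for c in columns if c not in stats.columns]
        if missing:
            raise UsageError(f"p-value columns not present: {', '.join(missing)}")
        stats = stats[list(columns)]
    if stats.shape[1] == 0:
        raise UsageError("no p-value columns selected")
    p_best = stats.min(axis=1, skipna=True)
    selected = {str(s): float(p) for s, p in p_best.items()
                if pd.notna(p) and p <= p_cutoff}
    if not selected:
        logger.warning("no gene-set passed the significance cutoff %g", p_cutoff)
    return selected


def all_pairs_spl(network: nx.Graph, sources: set[str]) -> SplTable:
    """Shortest path length between every pair of source nodes.

    Computed by breadth-first traversal from each source over the *full*
    interaction network (every edge counts 1).  Sources absent from the
    network are dropped with a warning; unreachable pairs are absent from
    the returned table.
    """
    present = sorted(s for s in sources if s in network)
    dropped = sorted(set(sources) - set(present))
    if dropped:
        logger.warning("%d significant set(s) absent from the interaction "
                       "network, dropped: %s", len(dropped), ", ".join(dropped))
    spl: SplTable = {}
    for i, src in enumerate(present):
        dist = nx.single_source_shortest_path_length(network, src)
        for dst in present[i + 1:]:
            if dst in dist:
                spl[frozenset((src, dst))] = int(dist[dst])
    return spl


def build_edges(significant: set[str], spl: SplTable, spl_cutoff: int) -> EdgeSet:
    """Candidate visualization edges: pairs with finite SPL below the cutoff.

    The cutoff is strict (SPL < spl_cutoff); unreachable pairs never get an
    edge.  Each edge carries its SPL.
    """
    if int(spl_cutoff) != spl_cutoff or spl_cutoff < 2:
        raise UsageError(f"spl_cutoff must be an integer >= 2, got {spl_cutoff}")
    return {pair: d for pair, d in spl.items()
            if pair <= set(significant) and d < spl_cutoff}


def prune_best_edges(edges: EdgeSet) -> EdgeSet:
    """Keep, per node, only incident edges with that node's minimal SPL.

    An edge survives when its SPL equals the minimum over the incident
    edges of at least one endpoint (ties all kept), so a node may retain a
    thinner edge that is the best one of a neighbouring node.  No node loses
    all its edges: its minimal edge is by definition kept.
    """
    best: dict[str, int] = {}
    for pair, d in edges.items():
        for node in pair:
            if node not in best or d < best[node]:
                best[node] = d
    return {pair: d for pair, d in edges.items()
            if any(d == best[node] for node in pair)}


def assemble_visualization_network(significant: dict[str, float],
                                   edges: EdgeSet,
                                   node_style: dict[str, dict],
                                   edge_thickness_fn) -> nx.Graph:
    """Build the final visualization network with all attributes attached.

    Nodes are all significant sets (isolated ones included), each with
    ``p_best``, ``size``, ``direction_score`` and ``color``; edges carry
    ``spl`` and ``thickness``.
    """
    if not significant:
        logger.warning("assembling an empty visualization network")
    viznet = nx.Graph()
    for set_id, p_best in sorted(significant.items()):
        try:
            style = node_style[set_id]
        except KeyError:
            raise RuntimeError(f"styling attributes missing for node {set_id!r}") from None
        viznet.add_node(set_id, p_best=p_best, **style)
    for pair, spl in sorted(edges.items(), key=lambda kv: tuple(sorted(kv[0]))):
        u, v = sorted(pair)
        viznet.add_edge(u, v, spl=spl, thickness=edge_thickness_fn(spl))
    return viznet


def reduce_network(stats: pd.DataFrame,
                   network: nx.Graph,
                   collection: dict[str, set[str]] | None = None,
                   gls: pd.DataFrame | None = None,
                   config: Config | None = None,
                   columns: list[str] | None = None) -> nx.Graph:
    """Run the full reduction: filter, SPL, edges, optional pruning, styling.

    Node color comes from member-gene statistics when both the collection
    and the gene-level table are given; otherwise it falls back to the
    directionality classes of the gene-set statistics table (distinct-up vs
    distinct-down p-values), and to neutral when neither is available.
    """
    config = config or Config()
    significant = filter_significant(stats, config.p_cutoff, columns)
    in_network = {s: p for s, p in significant.items() if s in network}
    spl = all_pairs_spl(network, set(significant))
    edges = build_edges(set(in_network), spl, config.spl_cutoff)
    if config.prune:
        edges = prune_best_edges(edges)

    use_gene_level = collection is not None and gls is not None
    node_style: dict[str, dict] = {}
    for set_id, p_best in in_network.items():
        if use_gene_level and set_id in collection:
            score = direction_score(set_id, collection, gls, config.gene_p_cutoff)
        else:
            score = directionality_fallback_score(stats.loc[set_id]) \
                if set_id in stats.index else 0.0
        node_style[set_id] = {
            "size": node_size(p_best, config.style),
            "direction_score": score,
            "color": score_to_color(score, config.style),
        }
    return assemble_visualization_network(
        in_network, edges, node_style,
        lambda spl_val: edge_thickness(spl_val, config.spl_cutoff, config.style))
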