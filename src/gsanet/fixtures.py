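"""Synthetic input bundles with known ground truth.

Real inputs for this tool come from a gene-set analysis of an expression
dataset against metabolite gene-sets of a genome-scale metabolic model,
plus the model's metabolite-metabolite network.  The generator here
emulates the *statistical shape* of such inputs instead: a small-world
interaction network (ring lattice with rewiring, mimicking metabolic-
network locality), a planted connected module of significant gene-sets
with a clear separation between planted and background p-values, and
member genes with coherent fold-change signs per planted direction.  The
planted truth makes end-to-end recovery testable without any downloads.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, UsageError

logger = logging.getLogger(__name__)

P_COLUMNS = ["non-directional", "distinct-up", "distinct-down"]


@dataclass
class ToyCase:
    """A synthetic input bundle plus its planted ground truth."""

    network: nx.Graph
    gss: pd.DataFrame                   # gene-set p-values, columns P_COLUMNS
    gsc: dict[str, set[str]]            # gene-set membership
    gls: pd.DataFrame                   # gene-level p / fc
    truth_sets: set[str]                # planted significant set ids
    truth_edges: set[frozenset]         # edges of the planted module (in network)
    truth_direction: dict[str, int]     # planted direction per set, +1 / -1
    p_cutoff: float
    spl_cutoff: int


def _connected_module(graph: nx.Graph, size: int,
                      rng: np.random.Generator) -> list[str]:
    """Grow a connected node subset of the requested size by random BFS."""
    nodes = sorted(graph.nodes)
    start = nodes[rng.integers(len(nodes))]
    module = [start]
    frontier = sorted(graph.neighbors(start))
    while len(module) < size and frontier:
        nxt = frontier.pop(rng.integers(len(frontier)))
        if nxt in module:
            continue
        module.append(nxt)
        frontier.extend(n for n in sorted(graph.neighbors(nxt))
                        if n not in module and n not in frontier)
    return module


def make_toy_case(seed: int,
                  n_sets: int = 50,
                  n_genes: int = 400,
                  module_size: int = 5,
                  p_cutoff: float = 0.05,
                  spl_cutoff: int = 5) -> ToyCase:
    """Generate a deterministic toy case with a planted significant module.

    The interaction network is a connected small-world graph over ``n_sets``
    gene-sets (ring lattice, degree 4, rewiring probability 0.1).  A
    connected module of ``module_size`` sets is planted with p-values
    uniform on (0, p_cutoff/2]; all other sets draw p-values uniform on
    (2*p_cutoff, 1], so the significance boundary is unambiguous.  Each set
    has 5-20 member genes; planted sets use disjoint gene pools so their
    planted directions (+1 or -1, assigned at random) translate into
    coherent fold-change signs with small gene-level p-values; background
    genes get null statistics.

    ``module_size = 0`` yields a valid case with no significant set.
    """
    if n_sets < 10:
        raise UsageError(f"n_sets must be >= 10, got {n_sets}")
    if not 0 <= module_size < n_sets:
        raise UsageError(f"module_size must be in [0, n_sets), got {module_size}")
    rng = np.random.default_rng(seed)
    set_ids = [f"GS{i:03d}" for i in range(n_sets)]
    graph_seed = int(rng.integers(2**31 - 1))
    raw = nx.connected_watts_strogatz_graph(n_sets, k=4, p=0.1, seed=graph_seed)
    network = nx.relabel_nodes(raw, {i: set_ids[i] for i in range(n_sets)})

    # plant a connected module whose pairwise SPLs all clear the cutoff
    module: list[str] = []
    for attempt in range(10):
        if module_size == 0:
            break
        candidate = _connected_module(network, module_size, rng)
        if len(candidate) < module_size:
            logger.info("module growth stalled (attempt %d), retrying", attempt + 1)
            continue
        max_spl = max(nx.single_source_shortest_path_length(network, u)[v]
                      for u in candidate for v in candidate)
        if max_spl < spl_cutoff:
            module = candidate
            break
        logger.info("planted module too spread (max SPL %d, attempt %d), retrying",
                    max_spl, attempt + 1)
    else:
        raise UsageError(
            f"could not plant a connected module of size {module_size} with "
            f"pairwise SPL < {spl_cutoff} in 10 attempts")

    truth_sets = set(module)
    truth_edges = {frozenset((u, v))
                   for u, v in network.subgraph(module).edges()}
    truth_direction = {s: int(rng.choice([-1, 1])) for s in sorted(truth_sets)}

    # gene-set p-values: planted well below cutoff, background well above
    gss = pd.DataFrame(index=pd.Index(set_ids, name="set_id"),
                       columns=P_COLUMNS, dtype=float)
    for s in set_ids:
        if s in truth_sets:
            p = float(rng.uniform(1e-8, p_cutoff / 2))
            d = truth_direction[s]
            gss.loc[s] = [p,
                          p if d > 0 else float(rng.uniform(0.5, 1.0)),
                          p if d < 0 else float(rng.uniform(0.5, 1.0))]
        else:
            gss.loc[s] = rng.uniform(2 * p_cutoff, 1.0, size=3)

    # membership: planted sets draw from disjoint gene pools so planted
    # directions stay coherent; background sets sample freely (overlap allowed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    n_planted_pool = module_size * 20
    if n_planted_pool > n_genes // 2:
        raise UsageError("n_genes too small for the requested module_size")
    gsc: dict[str, set[str]] = {}
    gls = pd.DataFrame({"p": rng.uniform(0.2, 1.0, size=n_genes),
                        "fc": rng.normal(0.0, 0.5, size=n_genes)},
                       index=pd.Index(gene_ids, name="gene_id"))
    for k, s in enumerate(sorted(truth_sets)):
        pool = gene_ids[k * 20:(k + 1) * 20]
        size = int(rng.integers(5, 21))
        members = sorted(rng.choice(pool, size=size, replace=False))
        gsc[s] = set(members)
        d = truth_direction[s]
        for g in members:
            gls.loc[g, "p"] = float(rng.uniform(1e-8, 0.01))
            gls.loc[g, "fc"] = d * float(rng.uniform(0.5, 3.0))
    background_pool = gene_ids[n_planted_pool:]
    for s in set_ids:
        if s in truth_sets:
            continue
        size = int(rng.integers(5, 21))
        gsc[s] = set(rng.choice(background_pool, size=size, replace=False))

    return ToyCase(network=network, gss=gss, gsc=gsc, gls=gls,
                   truth_sets=truth_sets, truth_edges=truth_edges,
                   truth_direction=truth_direction,
                   p_cutoff=p_cutoff, spl_cutoff=spl_cutoff)


def make_caption_like_case() -> ToyCase:
    """Hand-built worked example with known shortest path lengths.

    Four significant gene-sets A, B, C, D sit in a chain of non-significant
    intermediates such that SPL(A,B) = 3, SPL(C,D) = 4 and every cross-pair
    SPL is >= 5.  With an SPL cutoff of 5 the reduction therefore draws
    exactly the edges A-B and C-D, the former thicker than the latter; with
    cutoff 4 only A-B survives, and with cutoff 3 neither does.
    """
    network = nx.Graph()
    nx.add_path(network, ["A", "i1", "i2", "B"])            # SPL(A,B) = 3
    nx.add_path(network, ["C", "j1", "j2", "j3", "D"])      # SPL(C,D) = 4
    nx.add_path(network, ["B", "k1", "k2", "k3", "k4", "C"])  # SPL(B,C) = 5
    sig = {"A": 0.001, "B": 0.005, "C": 0.01, "D": 0.02}
    rows = {}
    for node in sorted(network.nodes):
        p = sig.get(node, 0.8)
        rows[node] = [p, p if node in sig else 0.9, 0.9]
    gss = pd.DataFrame.from_dict(rows, orient="index", columns=P_COLUMNS)
    gss.index.name = "set_id"
    gsc = {s: {f"{s.lower()}_gene{i}" for i in range(1, 4)} for s in sig}
    gene_rows = {}
    for s in sig:
        for i in range(1, 4):
            gene_rows[f"{s.lower()}_gene{i}"] = (0.001, 1.5)
    gls = pd.DataFrame.from_dict(gene_rows, orient="index", columns=["p", "fc"])
    gls.index.name = "gene_id"
    return ToyCase(network=network, gss=gss, gsc=gsc, gls=gls,
                   truth_sets=set(sig),
                   truth_edges={frozenset("AB"), frozenset("CD")},
                   truth_direction={s: 1 for s in sig},
                   p_cutoff=0.05, spl_cutoff=5)


def write_case(case: ToyCase, directory: str | os.PathLike,
               overwrite: bool = False) -> dict[str, str]:
    """Write a toy case as the tool's input file bundle plus truth manifest.

    Files: ``gss.tsv`` (gene-set statistics), ``gsc.tsv`` (two-column
    membership), ``gls.tsv`` (gene-level statistics), ``network.tsv``
    (edge list) and ``truth.txt`` (flat key=value manifest).  Refuses to
    clobber an existing bundle unless ``overwrite`` is set.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {name: os.path.join(directory, fname) for name, fname in [
        ("gss", "gss.tsv"), ("gsc", "gsc.tsv"), ("gls", "gls.tsv"),
        ("network", "network.tsv"), ("truth", "truth.txt")]}
    if not overwrite:
        existing = [p for p in paths.values() if os.path.exists(p)]
        if existing:
            raise InputError(
                f"refusing to overwrite existing bundle files: {existing} "
                f"(pass overwrite=True)")
    case.gss.to_csv(paths["gss"], sep="\t", na_rep="NA")
    with open(paths["gsc"], "w", encoding="utf-8") as fh:
        fh.write("set_id\tgene_id\n")
        for s in sorted(case.gsc):
            for g in sorted(case.gsc[s]):
                fh.write(f"{s}\t{g}\n")
    case.gls.to_csv(paths["gls"], sep="\t", na_rep="NA")
    with open(paths["network"], "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in case.network.edges()):
            fh.write(f"{u}\t{v}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(f"planted_sets={','.join(sorted(case.truth_sets))}\n")
        edges = ";".join("-".join(sorted(e)) for e in sorted(
            case.truth_edges, key=lambda e: tuple(sorted(e))))
        fh.write(f"planted_edges={edges}\n")
        dirs = ";".join(f"{s}:{d:+d}" for s, d in sorted(case.truth_direction.items()))
        fh.write(f"planted_directions={dirs}\n")
        fh.write(f"p_cutoff={case.p_cutoff}\n")
        fh.write(f"spl_cutoff={case.spl_cutoff}\n")
    return paths
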