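"""Readers and writers for the tool's tabular inputs and graphML output.

Four tab-separated inputs feed the pipeline:

* gene-set statistics -- one row per gene-set, one or more p-value columns
  (typically the directionality classes of a gene-set analysis: distinct
  up/down, mixed up/down, non-directional);
* gene-set collection -- gene-set membership, as (set, gene) pairs or GMT;
* gene-level statistics -- per-gene p-value and signed fold-change;
* gene-set interaction network -- headerless undirected edge list over
  gene-set identifiers.

All tables are UTF-8, tab-separated, with a header row (the edge list is
headerless).  Identifiers are matched case-sensitively across files; silent
case-folding would hide data errors.  Missing p-values are permitted and
treated as non-significant downstream.

In-memory representations are deliberately plain: pandas DataFrames for the
statistics tables, a ``dict[str, set[str]]`` for the collection and a
:class:`networkx.Graph` for the network.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import InputError, UsageError, ValidationError
from .styling import StyleParams

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA", "NaN", "nan", "N/A", "na", "NULL", "None"}

#: recognised header names for the gene-level statistics table
_P_COLUMN_NAMES = {"p", "p-value", "pvalue", "p_value", "pval", "p.value"}
_FC_COLUMN_NAMES = {"fc", "foldchange", "fold-change", "fold_change",
                    "log2fc", "logfc", "log2foldchange"}


@dataclass
class Config:
    """Run-level parameters of the pipeline.

    Parameters
    ----------
    p_cutoff
        Gene-set significance cutoff in ``(0, 1]``; a set is kept when its
        best p-value is <= this (inclusive, so boundary sets survive).
    spl_cutoff
        Shortest-path-length cutoff, an integer >= 2.  An edge is drawn
        between two significant sets when their SPL in the full interaction
        network is strictly below this value.
    prune
        Whether to keep, per node, only its lowest-SPL edges.
    seed
        Seed for the force-directed layout.
    gene_p_cutoff
        Gene-level significance cutoff used when computing the direction
        score from member-gene statistics.
    style
        Visual-attribute parameters (node-size range, significance cap,
        edge-thickness range, color anchors).
    """

    p_cutoff: float = 0.05
    spl_cutoff: int = 5
    prune: bool = True
    seed: int = 42
    gene_p_cutoff: float = 0.05
    style: StyleParams = field(default_factory=StyleParams)

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff <= 1):
            raise UsageError(f"p_cutoff must be in (0, 1], got {self.p_cutoff}")
        if int(self.spl_cutoff) != self.spl_cutoff or self.spl_cutoff < 2:
            raise UsageError(f"spl_cutoff must be an integer >= 2, got {self.spl_cutoff}")
        self.spl_cutoff = int(self.spl_cutoff)
        if not (0 < self.gene_p_cutoff <= 1):
            raise UsageError(f"gene_p_cutoff must be in (0, 1], got {self.gene_p_cutoff}")
        if self.seed < 0:
            raise UsageError(f"seed must be non-negative, got {self.seed}")


def _require_file(path: str | os.PathLike) -> None:
    if not os.path.isfile(path):
        raise InputError(f"input file not found: {path}")


def read_gene_set_statistics(path: str | os.PathLike,
                             columns: list[str] | None = None) -> pd.DataFrame:
    """Read the gene-set statistics table.

    The first column holds gene-set identifiers; every remaining column is a
    p-value column (one per directionality class, with whatever header names
    the upstream gene-set analysis produced).

    Parameters
    ----------
    path
        TSV file with a header row.
    columns
        Optional subset of p-value columns to retain; default all.

    Returns
    -------
    pandas.DataFrame
        Indexed by set id, one float column per retained p-value class;
        missing values are NaN.
    """
    _require_file(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, comment=None)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no p-value columns found")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate set ids: {', '.join(map(str, dup))}")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise UsageError(
                f"requested p-value columns not in {path}: {', '.join(missing)} "
                f"(available: {', '.join(df.columns)})")
        df = df[list(columns)]
    out = pd.DataFrame(index=df.index.astype(str))
    out.index.name = df.index.name or "set_id"
    for col in df.columns:
        vals = []
        for set_id, raw in df[col].items():
            raw = raw.strip()
            if raw in _NA_STRINGS:
                vals.append(math.nan)
                continue
            try:
                p = float(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric p-value {raw!r} in row {set_id!r}, "
                    f"column {col!r}") from None
            if not (0 <= p <= 1):
                raise ValidationError(
                    f"{path}: p-value {p} outside [0, 1] in row {set_id!r}, "
                    f"column {col!r}")
            vals.append(p)
        out[col] = vals
    return out


def read_gene_set_collection(path: str | os.PathLike,
                             dialect: str = "two-column") -> dict[str, set[str]]:
    """Read gene-set membership.

    Dialects
    --------
    ``two-column``
        One ``set_id<TAB>gene_id`` pair per line, header row required.
    ``gmt``
        Standard GMT: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``,
        headerless.

    Repeated (set, gene) pairs collapse to one membership.
    """
    _require_file(path)
    members: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        if dialect == "two-column":
            header = fh.readline()  # discarded; content is positional
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 2 tab-separated fields, "
                        f"got {len(fields)}")
                set_id, gene_id = (f.strip() for f in fields)
                if not set_id or not gene_id:
                    raise ValidationError(f"{path}:{lineno}: empty identifier")
                members.setdefault(set_id, set()).add(gene_id)
        elif dialect == "gmt":
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValidationError(
                        f"{path}:{lineno}: GMT line needs set id, description "
                        f"and at least one gene")
                set_id = fields[0].strip()
                genes = {g.strip() for g in fields[2:] if g.strip()}
                if not genes:
                    raise ValidationError(f"{path}:{lineno}: gene-set {set_id!r} is empty")
                members.setdefault(set_id, set()).update(genes)
        else:
            raise UsageError(f"unknown gene-set collection dialect: {dialect!r}")
    if not members:
        raise ValidationError(f"{path}: no gene-set memberships parsed")
    return members


def read_gene_level_statistics(path: str | os.PathLike) -> pd.DataFrame:
    """Read per-gene statistics: p-value and signed fold-change.

    The first column holds gene ids; the p and fold-change columns are found
    by case-insensitive header match (``p``/``p-value``/... and
    ``FC``/``log2FC``/...).  The fold-change sign carries the direction of
    change and is preserved exactly.

    Returns
    -------
    pandas.DataFrame
        Indexed by gene id with float columns ``p`` and ``fc``; a missing
        p-value is NaN and is excluded from significance counts downstream.
    """
    _require_file(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene ids: {', '.join(map(str, dup))}")
    lower = {c.lower().strip(): c for c in df.columns}
    p_col = next((lower[n] for n in _P_COLUMN_NAMES if n in lower), None)
    fc_col = next((lower[n] for n in _FC_COLUMN_NAMES if n in lower), None)
    if p_col is None:
        raise ValidationError(
            f"{path}: no p-value column (looked for {sorted(_P_COLUMN_NAMES)})")
    if fc_col is None:
        raise ValidationError(
            f"{path}: no fold-change column (looked for {sorted(_FC_COLUMN_NAMES)}); "
            f"direction of change is undefined without it")

    def _num(raw: str, gene: str, col: str, bounded: bool) -> float:
        raw = raw.strip()
        if raw in _NA_STRINGS:
            return math.nan
        try:
            v = float(raw)
        except ValueError:
            raise ValidationError(
                f"{path}: non-numeric value {raw!r} in row {gene!r}, column {col!r}"
            ) from None
        if bounded and not (0 <= v <= 1):
            raise ValidationError(
                f"{path}: p-value {v} outside [0, 1] in row {gene!r}")
        if not bounded and not math.isfinite(v):
            raise ValidationError(
                f"{path}: non-finite fold-change in row {gene!r}")
        return v

    out = pd.DataFrame({
        "p": [_num(r, g, p_col, True) for g, r in df[p_col].items()],
        "fc": [_num(r, g, fc_col, False) for g, r in df[fc_col].items()],
    }, index=df.index.astype(str))
    out.index.name = "gene_id"
    return out


def read_interaction_network(path: str | os.PathLike,
                             nodes_path: str | os.PathLike | None = None) -> nx.Graph:
    """Read the gene-set interaction network as an undirected edge list.

    Each non-comment line is ``idA<TAB>idB`` (headerless; lines starting
    with ``#`` are ignored).  The result is a simple undirected graph:
    duplicate and reversed edges collapse, self-loop lines are dropped with
    a warning.  ``nodes_path`` may name a file with one id per line to add
    isolated nodes.
    """
    _require_file(path)
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            a, b = (f.strip() for f in fields)
            if not a or not b:
                raise ValidationError(f"{path}:{lineno}: empty node identifier")
            if a == b:
                logger.warning("%s:%d: self-loop on %r dropped", path, lineno, a)
                graph.add_node(a)
                continue
            graph.add_edge(a, b)
    if nodes_path is not None:
        _require_file(nodes_path)
        with open(nodes_path, encoding="utf-8") as fh:
            for line in fh:
                node = line.strip()
                if node and not node.startswith("#"):
                    graph.add_node(node)
    return graph


def write_graphml(viznet: nx.Graph,
                  layout: dict[str, tuple[float, float]],
                  path: str | os.PathLike) -> None:
    """Write the visualization network as graphML, Cytoscape-importable.

    Node attributes: ``label``, ``p_value``, ``size``, ``direction_score``,
    ``color`` (hex) plus layout ``x``/``y``; edge attributes: ``spl``
    (integer) and ``thickness``.  The file round-trips through any
    conforming graphML parser.
    """
    missing = [n for n in viznet.nodes if n not in layout]
    if missing:
        raise UsageError(f"layout missing coordinates for nodes: {missing}")
    out = nx.Graph()
    for node, attrs in viznet.nodes(data=True):
        x, y = layout[node]
        out.add_node(node,
                     label=str(node),
                     p_value=float(attrs["p_best"]),
                     size=float(attrs["size"]),
                     direction_score=float(attrs["direction_score"]),
                     color=str(attrs["color"]),
                     x=float(x), y=float(y))
    for u, v, attrs in viznet.edges(data=True):
        out.add_edge(u, v, spl=int(attrs["spl"]), thickness=float(attrs["thickness"]))
    try:
        nx.write_graphml(out, path)
    except OSError as exc:
        raise InputError(f"cannot write graphML to {path}: {exc}") from exc


def read_graphml(path: str | os.PathLike) -> tuple[nx.Graph, dict[str, tuple[float, float]]]:
    """Read a graphML file written by :func:`write_graphml`.

    Returns the visualization network (attribute names as used in-memory)
    and the layout, separating the serialized ``x``/``y`` back out.
    """
    _require_file(path)
    raw = nx.read_graphml(path)
    viznet = nx.Graph()
    layout: dict[str, tuple[float, float]] = {}
    for node, attrs in raw.nodes(data=True):
        viznet.add_node(node,
                        p_best=float(attrs["p_value"]),
                        size=float(attrs["size"]),
                        direction_score=float(attrs["direction_score"]),
                        color=str(attrs["color"]))
        layout[node] = (float(attrs["x"]), float(attrs["y"]))
    for u, v, attrs in raw.edges(data=True):
        viznet.add_edge(u, v, spl=int(attrs["spl"]), thickness=float(attrs["thickness"]))
    return viznet, layout
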