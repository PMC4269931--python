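"""Produce the two output figures: network plot and clustered heatmap.

The network figure draws the reduced visualization network with a seeded
force-directed (spring-embedder) layout; node size/color and edge thickness
come pre-computed on the graph.  The heatmap complements the network by
showing the signed gene-level evidence behind every gene-set in it: cell
value sign(fc) * min(-log10 p, cap) for member genes, with non-member cells
masked out in gray, and rows/columns ordered by agglomerative hierarchical
clustering (average linkage, Euclidean distance; non-member cells count as
0 for distances).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import matplotlib
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import UsageError
from .styling import StyleParams, _hex_to_rgb, score_to_color

logger = logging.getLogger(__name__)

FIGURE_FORMATS = ("png", "pdf", "svg")


@dataclass
class HeatmapMatrix:
    """Signed gene-level scores per (gene-set, gene) with clustering orders.

    ``values`` holds the signed score (0 for non-members); ``member`` is the
    membership mask, so a zero-valued member cell and a non-member cell stay
    distinguishable.  ``row_order``/``col_order`` are index permutations
    filled in by :func:`cluster_heatmap`.
    """

    values: pd.DataFrame
    member: pd.DataFrame
    row_order: list[int] = field(default_factory=list)
    col_order: list[int] = field(default_factory=list)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)


def build_heatmap_matrix(viznet: nx.Graph,
                         collection: dict[str, set[str]],
                         gls: pd.DataFrame,
                         sig_cap: float = 10.0) -> HeatmapMatrix:
    """Assemble the heatmap matrix for the gene-sets of the network.

    Rows are exactly the network's nodes; columns the union of their member
    genes that appear in the gene-level table.  A member gene with a missing
    p-value scores 0 but stays marked as a member.
    """
    rows = sorted(viznet.nodes)
    genes: set[str] = set()
    for set_id in rows:
        genes |= collection.get(set_id, set()) & set(gls.index)
    cols = sorted(genes)
    values = pd.DataFrame(0.0, index=rows, columns=cols)
    member = pd.DataFrame(False, index=rows, columns=cols)
    for set_id in rows:
        for gene in collection.get(set_id, set()) & genes:
            member.loc[set_id, gene] = True
            p = gls.loc[gene, "p"]
            fc = gls.loc[gene, "fc"]
            if pd.isna(p) or fc == 0:
                continue
            neglog = sig_cap if p == 0 else min(-math.log10(p), sig_cap)
            values.loc[set_id, gene] = math.copysign(neglog, fc)
    return HeatmapMatrix(values=values, member=member)


def cluster_heatmap(matrix: HeatmapMatrix) -> HeatmapMatrix:
    """Order rows and columns by agglomerative hierarchical clustering.

    Average linkage on Euclidean distance, rows and columns independently;
    an axis of length 1 keeps the identity order.  Deterministic for a fixed
    input matrix.
    """
    if matrix.values.shape[0] < 1 or matrix.values.shape[1] < 1:
        raise UsageError("heatmap needs at least one row and one column")

    def _order(data: np.ndarray) -> list[int]:
        if data.shape[0] == 1:
            return [0]
        return [int(i) for i in leaves_list(linkage(data, method="average",
                                                    metric="euclidean"))]

    matrix.row_order = _order(matrix.values.to_numpy())
    matrix.col_order = _order(matrix.values.to_numpy().T)
    return matrix


def compute_layout(viznet: nx.Graph, seed: int) -> dict[str, tuple[float, float]]:
    """Seeded force-directed layout with non-overlapping components.

    Each connected component gets its own spring-embedder layout (seeded,
    hence deterministic), is rescaled to a unit bounding box and the boxes
    are tiled left to right with a margin.  A single node lands at the
    origin; an empty network yields an empty layout.
    """
    if len(viznet) == 0:
        return {}
    components = sorted(nx.connected_components(viznet), key=lambda c: sorted(c)[0])
    layout: dict[str, tuple[float, float]] = {}
    offset_x = 0.0
    margin = 0.5
    for i, comp in enumerate(components):
        sub = viznet.subgraph(comp)
        if len(sub) == 1:
            pos = {next(iter(comp)): np.array([0.0, 0.0])}
            width = 0.0
        else:
            pos = nx.spring_layout(sub, seed=seed + i, iterations=100)
            xs = np.array([p[0] for p in pos.values()])
            ys = np.array([p[1] for p in pos.values()])
            span = max(xs.max() - xs.min(), ys.max() - ys.min(), 1e-9)
            pos = {n: np.array([(p[0] - xs.min()) / span, (p[1] - ys.min()) / span])
                   for n, p in pos.items()}
            width = (xs.max() - xs.min()) / span
        for node, p in pos.items():
            layout[node] = (float(p[0] + offset_x), float(p[1]))
        offset_x += width + margin
    return layout


def render_network(viznet: nx.Graph,
                   layout: dict[str, tuple[float, float]],
                   path: str,
                   fmt: str = "png") -> None:
    """Draw the visualization network to an image file.

    Nodes appear at their layout coordinates with the styled size and color
    and a text label; edges use the styled thickness.  An empty network
    produces a figure carrying an explanatory message rather than an error.
    """
    if fmt not in FIGURE_FORMATS:
        raise UsageError(f"unsupported figure format {fmt!r}; choose from {FIGURE_FORMATS}")
    missing = [n for n in viznet.nodes if n not in layout]
    if missing:
        raise UsageError(f"layout missing coordinates for nodes: {missing}")
    with matplotlib.rc_context({"svg.fonttype": "none"}):
        fig, ax = plt.subplots(figsize=(8, 6))
        if len(viznet) == 0:
            ax.text(0.5, 0.5, "no significant gene-sets to display",
                    ha="center", va="center", transform=ax.transAxes)
            ax.set_axis_off()
        else:
            for u, v, attrs in viznet.edges(data=True):
                (x0, y0), (x1, y1) = layout[u], layout[v]
                ax.plot([x0, x1], [y0, y1], color="0.55",
                        linewidth=attrs["thickness"], zorder=1)
            xs = [layout[n][0] for n in viznet.nodes]
            ys = [layout[n][1] for n in viznet.nodes]
            sizes = [viznet.nodes[n]["size"] ** 2 for n in viznet.nodes]
            colors = [viznet.nodes[n]["color"] for n in viznet.nodes]
            ax.scatter(xs, ys, s=sizes, c=colors, edgecolors="0.2",
                       linewidths=0.8, zorder=2)
            for node in viznet.nodes:
                x, y = layout[node]
                ax.annotate(str(node), (x, y), textcoords="offset points",
                            xytext=(6, 6), fontsize=8, zorder=3)
            ax.set_axis_off()
            ax.margins(0.15)
        fig.savefig(path, format=fmt, bbox_inches="tight")
        plt.close(fig)


def heatmap_cell_colors(matrix: HeatmapMatrix,
                        params: StyleParams,
                        nonmember_gray: str = "#BDBDBD") -> np.ndarray:
    """RGB color per heatmap cell, rows/columns in clustered order.

    Member cells use the same diverging scale as node colors (value
    normalized by sig_cap); non-member cells take a distinct neutral gray so
    they never collide with a zero-valued member cell.
    """
    rows = matrix.row_order or list(range(matrix.values.shape[0]))
    cols = matrix.col_order or list(range(matrix.values.shape[1]))
    vals = matrix.values.to_numpy()[np.ix_(rows, cols)]
    memb = matrix.member.to_numpy()[np.ix_(rows, cols)]
    out = np.empty(vals.shape + (3,), dtype=float)
    gray = np.array(_hex_to_rgb(nonmember_gray)) / 255.0
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            if not memb[i, j]:
                out[i, j] = gray
            else:
                score = max(-1.0, min(1.0, vals[i, j] / params.sig_cap))
                out[i, j] = np.array(_hex_to_rgb(score_to_color(score, params))) / 255.0
    return out


def render_heatmap(matrix: HeatmapMatrix,
                   path: str,
                   fmt: str = "png",
                   params: StyleParams | None = None) -> None:
    """Draw the clustered gene-level heatmap to an image file."""
    if fmt not in FIGURE_FORMATS:
        raise UsageError(f"unsupported figure format {fmt!r}; choose from {FIGURE_FORMATS}")
    params = params or StyleParams()
    rows = matrix.row_order or list(range(matrix.values.shape[0]))
    cols = matrix.col_order or list(range(matrix.values.shape[1]))
    colors = heatmap_cell_colors(matrix, params)
    n_rows, n_cols = colors.shape[:2]
    with matplotlib.rc_context({"svg.fonttype": "none"}):
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.25 * n_cols + 2), max(3.0, 0.3 * n_rows + 1.5)))
        ax.imshow(colors, aspect="auto", interpolation="nearest")
        ax.set_xticks(range(n_cols))
        ax.set_xticklabels([matrix.col_ids[j] for j in cols], rotation=90, fontsize=7)
        ax.set_yticks(range(n_rows))
        ax.set_yticklabels([matrix.row_ids[i] for i in rows], fontsize=8)
        ax.set_xlabel("genes")
        ax.set_ylabel("gene-sets")
        fig.savefig(path, format=fmt, bbox_inches="tight")
        plt.close(fig)
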