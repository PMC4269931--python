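# Methods

## Model and procedure

`gsanet` treats gene-sets as interacting biological entities. The input is
the output of any gene-set analysis (per-set p-values, optionally split
into directionality classes such as distinct-up/distinct-down/mixed/
non-directional), the gene-set interaction network (an undirected, simple,
unweighted graph over set identifiers), and optionally the gene membership
of the sets plus the per-gene statistics (p-value, signed fold-change) that
fed the GSA.

The reduction has four steps:

1. **Significance filter.** A set is selected when its best p-value —
   the minimum over the chosen p-value columns, ignoring missing values —
   satisfies p ≤ `p_cutoff`. The cutoff is *inclusive*, so a set sitting
   exactly at the threshold is kept; the minimum over classes is the most
   permissive combination ("significant in any class"). Sets with every
   value missing never pass.
2. **Shortest path lengths.** SPL(u, v) is the minimum edge count of any
   path between u and v in the *full* interaction network, computed by
   breadth-first traversal from each selected node. Computing on the full
   network is essential: the biologically meaningful proximity of two
   significant sets is usually mediated by non-significant intermediates,
   and restricting paths to the significant subgraph would destroy exactly
   the signal the tool exists to show. Unreachable pairs carry no distance
   and never receive an edge (rather than an infinite-thickness artifact).
3. **Edge construction.** An edge joins two selected sets when
   SPL < `spl_cutoff` (*strict*, so cutoff 5 admits SPL 1–4). The cutoff is
   the user's notion of "still biologically connected".
4. **Best-edge pruning** (optional, on by default). For each node, let
   m(node) be the minimal SPL among its incident candidate edges; an edge
   {u, v} survives iff its SPL equals m(u) or m(v). Ties are all kept, a
   node can retain a thin edge because it is the best edge of its
   neighbour, and no node can lose all of its edges (its own minimal edge
   always survives). Pruning declutters hub-heavy networks without
   disconnecting any displayed set.

Selected sets absent from the interaction network are dropped with a
warning (there is no defined proximity for them); selected sets that are in
the network but end up with no edge are kept as isolated nodes.

## Visual attribute maps

* **Node size** = `size_min + (size_max − size_min) · min(−log10 p, sig_cap)/sig_cap`.
  The cap (default 10) keeps one extreme p-value from flattening the scale;
  p = 0 saturates at the cap with a warning. Defaults: sizes 10–40 display
  points.
* **Node color** comes from the direction score in [−1, 1]: among member
  genes present in the gene-level table with p ≤ `gene_p_cutoff`
  (default 0.05, conventional), the score is (n_up − n_down)/(n_up + n_down)
  by fold-change sign (fc = 0 counts as neither; no passing gene scores 0).
  The score is mapped by linear interpolation on a blue–neutral–red
  diverging scale (anchors #2166AC / #F7F7F7 / #B2182B, the RdBu extremes:
  red = up-regulated, blue = down-regulated). Without gene-level input the
  sign falls back to whichever of the distinct-up/distinct-down class
  p-values is smaller, with magnitude min(1, log10(p_other/p_winner)) — a
  deliberately conservative surrogate that goes neutral on ties or missing
  classes.
* **Edge thickness** = `thick_min + (thick_max − thick_min) ·
  (spl_cutoff − 1 − spl)/(spl_cutoff − 2)` for `spl_cutoff > 2` (else
  `thick_max`): strictly decreasing in SPL, SPL 1 thickest, the largest
  admissible SPL thinnest. Defaults 0.5–4.0 line widths.

All style constants are package choices, configurable through
`StyleParams`; only their monotonicity and anchor behaviour are contractual.

## Figures

The **network figure** uses a Fruchterman–Reingold spring embedding
(~100 iterations) with seeded initialization, so a fixed (network, seed)
pair reproduces coordinates exactly. Each connected component is laid out
independently, rescaled to a unit bounding box and tiled left-to-right with
a margin, which guarantees components never overlap; a lone node sits at
the origin. Labels are offset automatically from node centers.

The **heatmap** shows, for every displayed set, the signed gene-level score
sign(fc)·min(−log10 p, sig_cap) of each member gene found in the gene-level
table; a member gene with a missing p-value scores 0 but remains visually a
member, while non-member cells are masked in neutral gray — so "member,
unchanged" and "not a member" are always distinguishable. Rows and columns
are ordered by agglomerative hierarchical clustering with average linkage
on Euclidean distance (non-member cells count as 0 for distances); the
paper-of-record for the clustering is the SciPy implementation, checked in
the tests against a naive pairwise-distance agglomeration. Axes of length 1
keep identity order.

## Synthetic data generator

Real inputs would come from a GSA of an expression dataset against, e.g.,
metabolite gene-sets of a genome-scale metabolic model. The generator
emulates their statistical shape instead:

* **Topology**: a connected small-world graph (ring lattice of degree 4,
  rewiring probability 0.1) over 50 gene-sets by default — local
  neighbourhood structure with occasional shortcuts, qualitatively like a
  metabolite-metabolite network.
* **Planted truth**: a connected module of 5 sets (grown by random BFS,
  re-drawn up to 10 times until its pairwise SPLs in the full network all
  clear the SPL cutoff) receives p-values uniform on (0, p_cutoff/2]; all
  other sets draw from (2·p_cutoff, 1]. The separation band makes the
  intended significance labelling unambiguous — this is a strong-effect
  regime by design.
* **Genes**: 400 genes; each set has 5–20 members. Planted sets draw from
  disjoint per-set pools so each set's planted direction (±1) can be
  expressed as coherent fold-change signs (|fc| in [0.5, 3], p ≤ 0.01)
  without cross-set conflicts; background sets sample freely from the
  remaining pool (overlap allowed), and background genes carry null
  statistics (p ≥ 0.2, fc ~ N(0, 0.5)).

What passing tests on these cases show: the pipeline's selection, SPL
proximity, pruning, direction scoring and rendering behave exactly as
specified when effects are clearly separated. What they do not show:
behaviour under realistic GSA noise — correlated p-values, sets straddling
the cutoff, partially coherent fold-changes, or interaction networks with
hubs and degree heterogeneity unlike a small-world graph. The tool itself
treats p-values as opaque (it applies no multiple-testing correction of its
own; adjust upstream if desired).

A separate hand-built case encodes a worked example with known distances —
two significant pairs at SPL 3 and SPL 4 and all cross-pairs at SPL ≥ 5 —
used to pin down the strict-cutoff and thickness-ordering semantics.

## Numerical and design choices

* Identifier matching is case-sensitive exact string match across files;
  silent case-folding would hide data errors. No identifier-namespace
  conversion is attempted.
* Missing p-values are allowed everywhere and always mean "no evidence"
  (never significant, never counted).
* The SPL table stores each unordered pair once; self-distances are never
  stored; unreachable pairs are absent rather than sentinel-valued.
* Pruning, iteration and serialization all sort identifiers first, so
  outputs are independent of input line order and dict iteration order;
  byte-identical graphML across runs is a tested guarantee.
* The interaction network is unweighted and undirected; every edge counts
  1 toward SPL. Weighted or directed networks are out of scope.
* Gene-set statistics tables may carry any column names; the directionality
  fallback specifically looks for `distinct-up`/`distinct-down`.

## Problem sizes

The default test and acceptance workloads use 100 random graphs with at
most 15 nodes for the shortest-path oracle comparison, 100 random candidate
edge sets for pruning soundness, and 20 synthetic 50-set cases for
planted-module recovery — sizes at which the exhaustive oracles are exact
and the whole suite runs in seconds.

## Known limitations

* Node label placement is automatic; dense networks may need the graphML
  export and Cytoscape for publication-quality label layout.
* The direction score weighs every passing member gene equally; a set with
  one strong driver gene and many weak opposing genes can score near 0.
* The heatmap is drawn without dendrograms; the clustering orders are
  available on the `HeatmapMatrix` if callers want to draw their own.
* Equivalence with any other implementation's exact color/size formulas is
  not claimed; only the documented monotonicity and anchors are.
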