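# gsanet

Network-based visualization of gene-set analysis results.

## The problem

Gene-set analysis (GSA) condenses high-throughput data (typically a
differential-expression experiment) into per-set p-values, but its output is
usually consumed as a flat ranked list or a clustered heatmap. When the
gene-sets are biological entities that interact — the canonical example is
metabolite gene-sets, where each metabolite's set holds the genes of the
reactions it participates in and two metabolites are linked whenever they
share a reaction — that list hides the most interesting structure: several
significant sets may sit next to each other in the interaction network and
jointly mark a regulated pathway, even when they share no genes at all.

`gsanet` makes that structure visible. Given per-set p-values and a
user-defined gene-set interaction network, it:

1. **filters** the gene-sets to those with best p-value ≤ a cutoff
   (best = minimum over the supplied directionality-class columns);
2. computes the **shortest path length (SPL)** between every pair of
   selected sets *on the full interaction network*, so paths may run
   through non-significant intermediates;
3. draws an edge between two selected sets whenever SPL < an SPL cutoff,
   with thickness decreasing in SPL (SPL = 1, a direct interaction, is
   thickest);
4. optionally **prunes** to each node's lowest-SPL edges (ties kept, and an
   edge survives if it is the best edge of *either* endpoint);
5. renders the result with a seeded force-directed layout — node size
   encodes −log10 p (capped), node color encodes the direction of change of
   the member genes on a blue–neutral–red diverging scale — plus a
   complementary heatmap of the signed gene-level statistics,
   sign(fc)·min(−log10 p, cap), for every member gene of every displayed
   set, hierarchically clustered on both axes;
6. exports the styled network as **graphML** for further customization in
   Cytoscape.

Intended users are bioinformaticians who already run a GSA tool (any tool:
the inputs are plain TSV tables) and want an interpretable picture of how
the significant sets relate through a network they supply.

## Worked example

Generate a synthetic input bundle with a planted five-set module and run
the pipeline on it:

```bash
gsanet simulate --seed 1 --out-dir demo/bundle
gsanet run --gss demo/bundle/gss.tsv --network demo/bundle/network.tsv \
           --gsc demo/bundle/gsc.tsv --gls demo/bundle/gls.tsv --out demo/run
```

The run report (stdout, JSON; logs go to stderr):

```json
{
  "parameters": {
    "p_cutoff": 0.05,
    "spl_cutoff": 5,
    "prune": true,
    "seed": 42,
    "gene_p_cutoff": 0.05
  },
  "counts": {
    "input_sets": 50,
    "significant_sets": 5,
    "network_nodes": 5,
    "candidate_edges": 10,
    "drawn_edges": 5,
    "isolated_nodes": 0
  },
  "heatmap": true,
  "files": [
    "demo/run.network.png",
    "demo/run.heatmap.png",
    "demo/run.graphml"
  ]
}
```

Of the 50 input gene-sets, 5 pass the significance cutoff — exactly the
planted module. All 10 pairs among them lie within SPL 5 of each other
(candidate edges), and best-edge pruning keeps the 5 closest connections.
The network figure shows the five sets colored by their recovered direction
of change; the heatmap shows the member genes driving each one.

The same pipeline is available as library functions
(`gsanet.reduce_network`, `gsanet.compute_layout`,
`gsanet.build_heatmap_matrix`, ...) for notebook use.

### Input formats

| file | format |
|---|---|
| gene-set statistics | TSV, header; first column set id, remaining columns p-values (one per directionality class) |
| interaction network | headerless TSV edge list `idA<TAB>idB`; `#` comments allowed |
| gene-set collection (optional) | two-column TSV (`set_id`, `gene_id`) or GMT |
| gene-level statistics (optional) | TSV with gene id, p-value and signed fold-change columns |

The minimum input is the statistics table and the network; without the
optional files, node colors fall back to the GSA directionality classes and
the heatmap is skipped.

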