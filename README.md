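# netintegrity

Network-integrity analysis for prioritizing therapeutic-target genes and
interactions in biological networks.

Signaling pathways (EGFR, MAPK, ...) and protein-protein interaction (PPI)
networks can be interrogated as undirected graphs: a gene whose removal
badly degrades the network's connectivity is a candidate drug target, and a
gene that becomes critical only after the first target is removed is a
candidate resistance/redundancy mechanism. `netintegrity` implements that
workflow for computational biologists: centrality scoring, iterative-removal
re-ranking, restriction of a canonical pathway to the genes actually
expressed in a tissue or cell line, and rank-comparison statistics — as a
library plus a thin `netintegrity` command-line tool.

## Measures

For a simple undirected graph G = (V, E) with adjacency matrix A and node
degrees d_i:

- **Degree centrality** — c_d(i) = Σ_j a_ij, the number of incident edges.
- **Betweenness** — c_b(k) = Σ_{i<j} g_ikj / g_ij, where g_ij counts
  shortest i–j paths and g_ikj those passing through k; the edge analogue
  e_b(e) = Σ_{i<j} g_iej / g_ij sums the fractions traversing edge e
  (unnormalized, unordered pairs; disconnected pairs contribute 0).
- **Eigenvector centrality** — c_e(i) = (1/λ) Σ_j a_ij c_e(j) with λ the
  largest adjacency eigenvalue: the dominant eigenvector, reported
  non-negative with unit Euclidean norm.
- **Spectral gap centrality** — with the symmetric normalized Laplacian
  L_ii = 1 (d_i ≥ 1), L_ij = −1/√(d_i d_j) for edges, whose eigenvalues lie
  in [0, 2] with λ2 (the *spectral gap*) ≤ 1 for connected non-complete
  graphs and → 0 as the graph falls apart,

      c_s^h(i) = λ2(h-neighborhood of i) / log2(d_i)   for d_i > 1,
      c_s^h(i) = ∞                                      for d_i ≤ 1.

  **Lower** values mark more critical nodes; all other measures are
  higher-is-critical. h = 2 or 3 is a reasonable default for typical
  pathways.

Two ranking schemes: **by value** (sort once, competition ranks for ties)
and **by removal** (recompute the measure, delete the single most-critical
node or edge, repeat — the deletion order is the ranking). Rankings are
compared with Spearman's ρ and assembled across conditions into
heatmap-ready rank matrices with ranks beyond a cap bucketed as ">cap".

Reported `avg_degree` follows the edges-per-node convention |E|/|V| common
in pathway summaries; the conventional 2|E|/|V| is exposed as
`mean_degree`.

## Worked example

Build a toy three-cascade network (11 nodes: a shared source `SRC` and sink
`SNK` joined by three node-disjoint chains of three nodes, emulating
parallel MAPK-style cascades), plus a matching synthetic expression table:

```sh
$ netintegrity fixture --kind parallel_cascades --k 3 --length 3 --seed 7 \
      -o mapk_toy.sif --expression-out expr.tsv --fraction 0.3
wrote 11 nodes, 12 edges to mapk_toy.sif

$ netintegrity stats mapk_toy.sif
n_nodes	11
n_edges	12
avg_degree	1.09
density	0.22
n_components	1
```

avg_degree 1.09 = 12/11 (the |E|/|V| convention); density 0.22 = 12/55
possible edges. Spectral gap centrality with h = 2, ranked by iterative
removal:

```sh
$ netintegrity rank mapk_toy.sif --measure spectral_gap --scheme removal --h 2
item	rank
SNK	1
SRC	2
C1_02	3
C2_02	4
...
```

The shared sink and source are removed first (their 2-neighborhoods are the
least robust relative to their degree); after they are gone the cascade
midpoints `C1_02`, `C2_02`, `C3_02` follow — one per cascade, the redundancy
pattern that motivates removal-based ranking. How much the measures agree
(Spearman's ρ between value rankings over all 11 nodes):

```sh
$ netintegrity compare mapk_toy.sif --measures degree,betweenness,spectral_gap --scheme value
	degree	betweenness	spectral_gap
degree	1.00	0.74	0.68
betweenness	0.74	1.00	0.92
spectral_gap	0.68	0.92	1.00
```

Restrict the pathway to the genes expressed in a condition (RPKM ≥ 0.5;
strictly below the threshold is unexpressed):

```sh
$ netintegrity restrict mapk_toy.sif --expression expr.tsv --threshold 0.5 -o restricted.sif
kept 8 of 11 nodes, 8 of 12 edges
```

The same operations are available as functions (`netintegrity.build_graph`,
`spectral_gap_centrality`, `rank_by_removal`, `restrict_pathway`,
`ppi_subnetwork`, `spearman_rho`, `build_rank_matrix`, ...); see the module
docstrings and `docs/methods.md`.

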