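# Methods

## Graph model

All analyses operate on undirected simple graphs over opaque,
case-sensitive string node identifiers (typically HGNC symbols; no alias
resolution is attempted). Curated pathway exports are frequently directed,
duplicated, or self-referential; `build_graph` symmetrizes directed
records, collapses duplicates, drops self-loops, and logs the counts.
Isolated nodes and multiple connected components are first-class — a
pathway is often not one connected component, and several operations
(spectral gap of a disconnected graph, betweenness across components) are
defined with that in mind.

Summary statistics follow the conventions of published pathway tables:
`avg_degree` is |E|/|V| (edges per node — a 235-node, 249-edge pathway has
avg_degree 1.06), with the conventional mean degree 2|E|/|V| exposed
separately as `mean_degree`; `density` is m / (n(n−1)/2), undefined for
n < 2. Values are never rounded internally; `GraphStats.rounded()` applies
half-up rounding (not banker's) for report parity with printed 2-decimal
tables.

## Centrality measures

**Degree** and **betweenness** (node and edge) are delegated to networkx;
betweenness uses Brandes accumulation with `normalized=False`, which for
undirected graphs equals the unordered-pair sums Σ_{i<j} g_ikj/g_ij and
Σ_{i<j} g_iej/g_ij directly. Pairs in different components contribute 0
(0/0 := 0). For an edge {i, j}, the pair {i, j} itself contributes 1: the
edge is the unique shortest path between its endpoints. The test suite
checks both against an independent brute-force oracle that enumerates every
simple path per pair on graphs with ≤ 8 nodes.

**Eigenvector centrality** is computed by direct symmetric
eigendecomposition of the dense adjacency matrix (`numpy.linalg.eigh`),
oriented so the largest-magnitude entry is positive, clipped at 0, and
normalized to unit Euclidean length. Pathway-scale graphs (hundreds of
nodes) make the dense decomposition cheap and avoid power-iteration
convergence tuning. An edgeless graph raises: the dominant eigenvalue is 0
and the measure is undefined. On disconnected graphs the measure is
computed globally (not per component); when the dominant eigenvalue is
degenerate across components (gap < 1e−10) the returned vector is one
eigensolver-chosen representative of the eigenspace and a warning is
logged — rankings derived from it should not be trusted in that case.

**Normalized Laplacian.** Built explicitly in Chung's convention:
L_ii = 1 for d_i ≥ 1 and 0 for isolated nodes, L_ij = −1/√(d_i d_j) on
edges. Eigenvalues (via `eigvalsh`) lie in [0, 2]; the number of ≈0
eigenvalues (|λ| < 1e−8) equals the number of connected components, so the
spectral gap λ2 (second-smallest eigenvalue, ascending order) is 0 exactly
when the graph is disconnected, ≤ 1 for connected non-complete graphs, and
n/(n−1) for K_n.

**Spectral gap centrality.** c_s^h(i) = λ2(ball(i, h)) / log2(d_i), where
ball(i, h) is the subgraph induced on all nodes within h edges of i
(center included, hence connected), and d_i is i's degree in the *full*
graph, not within the ball — the degree is a property of the node, the
ball a probe of its surroundings. Nodes with d_i ≤ 1 map to +∞: log2(1)=0
would divide by zero, and a leaf (or isolated node, strictly less
connected still) cannot be structurally critical. Lower values are more
critical: a high-degree node whose neighborhood falls apart without it
scores low. The radius h trades locality for globality; h = 2 (default)
or 3 suits typical pathways.

## Ranking schemes

`rank_by_value` sorts once, orientation-aware (+∞ sorts last for spectral
gap). Ties get competition ranks (1, 2, 2, 4) for display and average
ranks (1, 2.5, 2.5, 4) for correlation — standard Spearman practice; tied
items are ordered lexicographically for reproducible output. Exact value
equality defines a tie here; value rankings are a single sort, so float
noise only reorders genuinely tied items within their group.

`rank_by_removal` deletes exactly one item per iteration — the only scheme
that yields a strict total order — recomputing the measure on the shrunken
graph each time. Selection is orientation-aware; ties break by higher
current degree, then lexicographically. Because Brandes accumulation can
differ by ~1e−15 between symmetry-equivalent nodes, candidate values
within a relative 1e−9 of the optimum are treated as tied before the
deterministic tie-break is applied. Degenerate tails: when every remaining
node is uninformative (betweenness/degree all 0; spectral gap all +∞;
eigenvector undefined because no edges remain), the remainder is ordered
by degree descending then lexicographically and assigned consecutive
ranks. +∞-valued nodes are never selected while a finite-valued node
remains. Edge removal ranking recomputes edge betweenness, removes the
top edge (lexicographic tie-break on the ordered endpoint pair), and
never touches the node set.

A consequence worth knowing when interpreting removal rankings of edges on
parallel-cascade topologies (k node-disjoint chains sharing a source and a
sink): after the first removal breaks one cascade, that cascade's chain
dangles from its single remaining attachment edge, which then carries all
shortest-path traffic for the dangling nodes and is removed next. Each
cascade therefore tends to absorb two consecutive removals (one per end)
before the process moves to the next cascade; the first k removals touch
all k cascades only for k = 2 (where mid-chain edges dominate instead).
The test suite pins this behavior against the brute-force oracle. The
practical reading stands — consecutive top edges spread over a *few*
distinct cascades rather than shredding one — but distinctness of the
first k is not a theorem for k ≥ 3.

`spearman_rho` uses `scipy.stats.spearmanr` over the items ranked in both
inputs (or an explicit subset, for table layouts where some cells are
blank), with average ranks for ties, and refuses fewer than 3 common
items. `build_rank_matrix` assembles per-condition rankings over the union
of items; ranks > cap collapse into a ">cap" bucket (cap 10 for nodes and
5 for edges in typical figures), while an item absent from a condition's
graph is NA — absent and low-ranked are distinct states. The optional
heatmap colors rank 1 dark red through the cap into blue, the bucket
darkest, NA white.

## Expression-conditioned restriction

Expression arrives either as binary expressed/unexpressed calls
(precomputed, e.g. by a microarray barcode method — deliberately not
reimplemented here) or as numeric RPKM-like levels thresholded at call
time: strictly below the threshold is unexpressed, so a gene exactly at
the threshold is expressed. 0.5 RPKM is the conservative default preset;
3.0 the aggressive one (removing roughly 40–60% of a typical pathway's
genes). `restrict_pathway` deletes unexpressed nodes with their incident
edges and returns the induced subgraph. Pathway genes absent from the
expression table follow an explicit policy, default `keep` (absence of
evidence is not evidence of absence), with `drop` selectable; counts are
logged. Continuous expression weighting is out of scope — expression acts
only as node presence/absence.

`ppi_subnetwork` induces the PPI subgraph on the intersection of a
pathway's gene set with the PPI node set, erroring on empty intersection
and logging how many pathway genes the PPI network lacks.

## Synthetic fixtures

The fixture generator produces the topologies the measures are designed to
discriminate: paths, cycles, stars, complete graphs, barbells (two cliques
and a bridge — betweenness's favorite), Erdős–Rényi G(n, p), and
`parallel_cascades(k, length)` — k node-disjoint chains sharing one source
and one sink (2 + k·length nodes, k·(length+1) edges), the redundant
signal-transduction motif (ERK1/2, JNK, p38 ...) that motivates
removal-based ranking; length 3 mirrors the three-tier kinase cascades of
MAPK-type pathways. Expression fixtures assign a seeded random subset of
round(fraction·n) genes values in [0, 0.5) and the rest values in [1, 10],
so the expressed set at threshold 0.5 is known exactly. All generation is
seeded; identical parameters yield identical outputs.

What the fixtures do not emulate: scale-free degree distributions, the
hub density of real PPI networks (thousands of edges), compound/complex
nodes of curated pathway formats, or biologically correlated expression.
Passing tests therefore certify the algorithms' contracts and closed-form
behavior, not recovery of any particular biological ranking.

## Numerical choices

- Eigenvalue assertions at 1e−8; values within 1e−12 of 0 treated as 0
  for disconnection detection; eigen-equation residual tolerance 1e−8.
- Removal-selection tie snapping at relative 1e−9 (above).
- Half-up rounding only at the reporting boundary, never internally.
- Dense eigendecompositions throughout: the intended inputs (pathways,
  pathway-induced PPI subnetworks, h-neighborhoods) are a few hundred
  nodes at most. Graphs with tens of thousands of nodes would need sparse
  solvers; that is a known limitation.

## Verification problem sizes

The test suite checks betweenness against brute-force path enumeration on
200 random graphs of ≤ 8 nodes, spectral bounds on 500 random graphs of
≤ 30 nodes, closed forms (K_n gap n/(n−1), star spectra, P3 spectrum
{0, 1, 2}, Spearman transposition 0.8), and published pathway summary
conventions on size-matched random graphs; the acceptance script rechecks
the two spectral bounds on freshly seeded 500-graph ensembles. These sizes
exercise every code path while keeping the whole suite in seconds.
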