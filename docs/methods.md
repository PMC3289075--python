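# Methods

This note records the model, the defaults and the numerical choices made
where the design was genuinely open.

## Random walk with restarts

The input is an undirected graph with strictly positive edge weights, no
self-loops and no isolated nodes (readers enforce all three; self-loops in
input files are dropped with a logged count, duplicate pairs resolve to
the maximum weight by default, configurable to `sum` or `first`).
Transition probabilities are the row-normalised weights.  For a restart
distribution `b` and restart probability `α`, the stationary vector solves
`x = α·b + (1 − α)·Pᵀx`; we compute it by power iteration initialised at
`x₀ = b`, stopping when the L1 distance between consecutive iterates falls
below `tol` (default `1e-10`, iteration cap 10 000 — at the default
`α = 0.6` convergence takes ~25 iterations since the residual contracts by
a factor `1 − α`).  The update conserves probability exactly, so no
renormalisation is applied; the final residual is stored in the vector's
metadata.

Because the fixed point is linear in `b`, the stationary vector of any
weighted start set is the convex combination `Σ w_s p_s / Σ w_s` of
single-seed vectors.  `rwr_single_all` therefore computes `p_s` for every
node once and optionally persists them, one array per seed, under a
directory keyed by a SHA-256 digest of the canonicalised edge list plus
(α, tol) — content-addressed, so renaming the input file does not defeat
the cache, while any change to weights, tolerance or restart probability
does.  A `meta.json` header (digest, α, tol, node order) makes each cache
self-describing; corrupt entries are recomputed with a warning.
Stationary vectors refuse to combine across mismatched (graph, α, tol).

## Node weights and cluster expansion

The node weight `w_v` is the sum of the weights of all edges incident to
`v` — the total evidence for `v`'s interactions.  In node-weighted mode
the restart mass over cluster members is `b_i = w_i / Σ_{j∈C} w_j`; in
uniform mode it is `1/|C|`, which reproduces the equal-restart (RRW)
expansion.  When all node weights are equal the two modes coincide; the
implementation detects this case and uses unit weights so the reduction
holds bitwise (exact argmax ties must break identically in both modes).

Expansion from a seed adds, at each step, the outside node with the
highest `p_C(v)` (ties break to the lexicographically smallest ID; node
order is sorted, so `argmax`'s first-hit rule implements this).  Stopping
rules, in order:

* size reached `max_size`;
* no outside node has positive probability (disconnected remainder);
* **early cutoff**: once `|C| ≥ min_size`, stop if the best outsider's
  probability is below `early_cutoff` × the probability at which the
  previous node was admitted.  This ratio form was chosen because the
  natural alternative — comparing outsiders against insider probabilities —
  is degenerate: insiders carry the restart mass (≥ α/|C|), so with
  α = 0.6 and a 0.5 cutoff even a perfect clique would stop at `min_size`.
  Against the previous admission the ratio stays ≈ 1 inside a homogeneous
  module and collapses at its boundary, which is the intended semantics of
  a cutoff searched over {0.5, 0.6, 0.7}.

### Score and statistical significance

The score of a cluster is the mean of `p_u(v)` over ordered pairs
`u ≠ v` of members.  Self-pairs are excluded — `p_u(u)` is dominated by
restart mass and would swamp the mean.  Significance is an empirical
p-value: draw `M` (default 999) uniform random node subsets of the same
size and report `(1 + #{score(R) > score(C)}) / (M + 1)`.  The strict
inequality matters: the add-one term already stands for the observed
cluster, so a draw that merely ties it (e.g. redraws the same subset in a
small graph) is not double-counted, and the best possible cluster of its
size attains exactly `1/(M+1)`.  The RNG stream derives from the master
seed *and* the sorted member list, making every cluster's p-value
deterministic and independent of evaluation order.  Subset sampling and
scoring are vectorised against the dense matrix `S[i,j] = p_i(j)`; this
matrix is O(n²) memory, appropriate for networks up to a few thousand
nodes (the intended scale), and per-cluster statistics are memoised within
a run.

### Candidate selection and de-duplication

Every intermediate cluster inside `[min_size, max_size]` is recorded; the
seed's candidate is the intermediate with minimal significance, with ties
resolved by higher score (judged at 1e-9, coarser than the walk tolerance,
so numerically identical scores compare as equal) and then by the *larger*
cluster.  Preferring the larger tied cluster is deliberate: in an exactly
symmetric module every subset of a clique has the same score and usually
the same Monte-Carlo p-value, and a smaller-first rule would
systematically truncate perfect complexes to `min_size`.  The same
ordering (significance ascending, score descending, size descending,
lexicographic members) drives the greedy overlap filter, which keeps a
candidate iff its overlap ratio with every kept cluster is at most the
threshold.  The overlap ratio is containment — intersection over the
smaller cluster — so near-subsets are treated as redundant; Jaccard is
available as a configuration switch.  Seeds are all nodes of the graph.
If `max_size < min_size` the window is empty and the run legitimately
returns no clusters.

Default parameters (α = 0.6, early cutoff 0.5, overlap threshold 0.3,
min size 4, max size 100) are the optima of the benchmark grid search;
`benchgen.table1_nwe_grid()` reproduces the searched 81-point grid.

## Evaluation statistics

Concordance between two protein sets defaults to Jaccard
(`|∩| / |∪|`): 1 iff identical, 0 iff disjoint, strictly below 1 for
proper subsets.  The squared-overlap form `|∩|² / (|s1||s2|)`, which
satisfies the same boundary properties, is available as a switch.
Cluster-wise precision is the best concordance against any catalog
complex; complex-wise recall mirrors it.  Quantitative precision averages
the non-zero cluster precisions weighted by `log |c|` (a given overlap
proportion is less likely by chance for a larger set; the log base
cancels); clusters that overlap nothing are excluded because the catalog
is incomplete and such clusters may be genuine novel complexes.
Quantitative recall averages over *all* complexes, unmatched ones
contributing zero.  Size-1 clusters would carry zero log weight; they are
skipped with a warning.  Evaluation filters both clusters and complexes
to size ≥ 4 by default, matching the minimum-size convention of the
curated catalogs.

## Synthetic benchmark generator

The generator emulates the structure of a curated-catalog benchmark
without requiring downloads:

* `synthesize_catalog` draws disjoint complexes with sizes from a
  truncated geometric on [4, 20] (p = 0.25) by default — small complexes
  dominate curated catalogs — with generated protein IDs.
* `test_graph` joins every within-complex pair (weight 1); shared pairs
  are stored once.
* `alter_graph` deletes `round(del·|E|)` original edges and adds
  `round(add·|E|)` uniformly sampled non-edges (never re-adding an
  original, never a self-loop); fractions are relative to the original
  edge count and rounding is half-away-from-zero.  Candidate non-edges
  are enumerated exactly, so the request fails loudly if the graph is too
  dense.
* `assign_weights` draws integers from `Uniform{u_min..100}` for original
  edges and `Uniform{1..u_max}` for added ones — high-regime signal,
  low-regime noise.
* `altered_graph_suite` runs the 2×2×2×2 grid (del ∈ {0.4, 0.8},
  add ∈ {0.4, 1.0}, u_min, u_max ∈ {30, 70}), one alteration per
  (del, add) reused across weightings, all sub-seeds derived
  deterministically from the master seed.
* `degree_preserving_shuffle` performs `round(k·|E|)` *successful* double
  edge swaps (a,b)+(c,d) → (a,d)+(c,b), each new edge inheriting the
  weight of the old edge sharing its first endpoint; degree sequence,
  edge count and weight multiset are invariant.  Swaps that would create
  self-loops or duplicates are rejected; exceeding 100× the target in
  attempts raises (e.g. a triangle admits no swap at all).  Counting
  successful rather than attempted swaps makes the nominal ratio the
  realised amount of randomisation.

What the generator does *not* emulate: overlapping complexes, the heavy
right tail of real degree distributions, and evidence weights correlated
with protein abundance.  Passing the planted-recovery tests therefore
demonstrates correctness of the machinery and qualitative robustness
trends, not performance on a real interactome.

Test and acceptance runs use catalogs of 5–10 complexes (≈ 30–80 proteins)
and 10 shuffle replicates; these sizes give stable statistics while
keeping the whole suite in seconds.

## GO-slim coverage

Coverage of a cluster by a term is the fraction of members annotated with
it; unannotated members stay in the denominator by definition, so
coverage penalises them.  The cluster's coverage over an aspect is the
maximum over terms, with ties broken to the lexicographically smallest
term for reproducible reports.  Frequency distributions use the half-open
bins (r − 0.1, r] for r = 0.1 … 1.0 plus an exact-zero bin (a size-4
cluster can only attain {0, 0.25, 0.5, 0.75, 1}); bin assignment rounds
at 1e-12 before comparing so float noise cannot shift a value across an
edge.  The significance–coverage association is the Pearson correlation
with the two-sided t-test `t = r√((n−2)/(1−r²))` on n − 2 degrees of
freedom (scipy's implementation; the test suite cross-checks it against
the explicit formula).  Raw significance values are used, untransformed.

## Known limitations

* The dense single-seed matrix makes memory O(n²); a 6 000-node
  interactome needs ≈ 300 MB, larger networks would need a sparse or
  blocked variant.
* Monte-Carlo significance has resolution 1/(M+1); ranking among several
  clusters tied at the floor falls back to score and size.
* The expansion is greedy and never removes a member; a poor early
  admission cannot be undone.
* Cluster files persist members and significance only; scores are not
  round-tripped.
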