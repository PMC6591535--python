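# Methods

This note records the model implemented by `ssnkit`, the parameters that
matter, the numerical choices, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one reading was
defensible.

## Symmetrized E-value distance

The distance between two sequences is the geometric mean of the two
directed E-values, d_ij = sqrt(E_ij · E_ji). E-values are the expected
number of chance alignments at a given score, so they are the natural
similarity currency of an all-vs-all BLASTp run; the geometric mean
symmetrizes on the log scale where E-values live. Numerically the product
is computed as `sqrt(E_ij)·sqrt(E_ji)` — squaring first would underflow
for E-values below ~1e-154 and silently fabricate zero distances — and
equal inputs short-circuit so that sqrt(E·E) == E exactly.

Parameters:

* **E_cap** (default 10, dimensionless): substituted for a missing search
  direction before the product. 10 is the conventional BLAST reporting
  ceiling, so "no hit reported" is read as "no better than threshold
  evidence"; this keeps the matrix total and errs toward larger distances.
  A query with no hits at all therefore sits at distance sqrt(cap·cap) =
  E_cap from every base sequence.
* Exact zeros are preserved as exact zeros, never floored to machine
  epsilon: the conservative-core analysis (below) is defined by literal
  zero distances.

Remote-homology distances from an iterative profile search reuse the same
symmetrization on the profile-search E-value table. (The source
formulation prints the same index twice in the profile-search distance;
we implement the symmetric form, the only reading consistent with the
BLASTp definition.)

The **NRMSD** diagnostic, sqrt(mean_i (1 − d_i^b / d_i^{b+q})²), measures
how much query distances computed against a fixed base dataset deviate
from distances computed with the query included. Pairs with both
distances zero count as perfect agreement (ratio 1); a zero base+query
distance against a nonzero base distance is undefined and raises. The
statistic responds linearly to a uniform relative perturbation ε (NRMSD ≈
ε for ε ≪ 1), which the tests verify; no dataset-specific bound is
asserted because the bound depends on the dataset.

## Minimum-span clustering

One MSC round links every unit to its nearest neighbor (distance ties
break to the lexicographically smallest neighbor id) and takes connected
components of the undirected link graph as clusters. The recursion
replaces clusters by units whose pairwise distances are single-linkage
minima over member pairs — so a superdistance at any level equals the
minimum over original sequence pairs — and repeats, up to `max_levels`
(default 3: sequences → clusters → families) or until everything merges.
The published description of the algorithm defers its details to earlier
work; the nearest-neighbor-link/connected-component recursion implemented
here is a reimplementation choice that satisfies every stated property
(hierarchical, no hyper-parameters, no preset cluster count, multi-level
output). Cluster counts strictly decrease between levels because every
link component has at least two members.

Each cluster-unit is named internally by its lexicographically smallest
member, which makes tie-breaking at coarser levels deterministic and makes
the whole hierarchy invariant under order-preserving renaming of inputs.

**Minimum spanning trees** use Kruskal with edges sorted by (distance,
(smaller id, larger id)); the lexicographic secondary key makes the tree
unique among ties and the output reproducible across platforms.

**Conservative cores.** The core of a cluster is its largest subset with
all pairwise distances exactly zero. Connected components of the
zero-distance graph are reduced to cliques greedily: repeatedly drop the
member with the most nonzero in-component pairs, removing the
lexicographically largest id among ties. Observed cores are cliques
already, so exact maximum-clique search (NP-hard) would buy nothing; the
greedy reduction is deterministic and its output always satisfies the
all-pairs-zero predicate (property-tested).

**Naming.** Clusters are grouped by the majority annotation prefix of
their members (2–3 alphanumerics; unannotated members count as `Un`) and
numbered 001, 002, ... by decreasing size, ties going to the cluster
holding the smallest id — the largest cluster of a family is always
`<prefix>001`.

## Similarity network and centrality

Edge lengths are d̃_uv = d_uv^q + δ with q = 0.01 and δ = 1e-200, weights
w_uv = 1/(d̃_uv + 1); diagonals of both matrices are 0. The tiny exponent
compresses distances spanning 150+ orders of magnitude into a workable
range (1e-100 ↦ 0.1); δ keeps lengths strictly positive so zero-distance
pairs still have finite shortest-path arithmetic. 0^q is defined as 0, so
w(d=0) = 1/(1+1e-200), indistinguishable from 1 in double precision.

* **Weighted degree**: row sums of W.
* **Closeness**: (|V_c|−1) divided by the sum of shortest-path lengths,
  with |V_c| the size of the node's connected component. Shortest paths
  are genuine path distances (Dijkstra over present edges): E-value
  distances violate the triangle inequality, so a two-hop route can be
  shorter than the direct edge. Isolated nodes get closeness 0.
* **Betweenness** (nodes and edges): unnormalized sums of
  g_jk(u)/g_jk over unordered pairs j < k with endpoints excluded.
  Shortest-path ties are counted with a relative length tolerance
  (default 1e-12, configurable): two path lengths are equal when
  |L1−L2| ≤ tol·max(L1, L2), absorbing float accumulation over δ-scale
  edges.
* **Eigenvector**: leading eigenpair of W by power iteration from the
  uniform vector, converged when successive unit-norm iterates differ by
  less than 1e-12 in the max norm (default cap 10 000 iterations,
  non-convergence raises with the iteration count). The result is
  normalized to unit Euclidean norm with nonnegative entries.

Numerical choices worth stating:

* **δ-scale edges and path counting.** δ = 1e-200 is far below the float
  ulp of any d^q-scale path length, so a detour through a zero-distance
  pair has a mathematically longer length (+δ per extra hop) that floats
  cannot represent. The path-count recursion therefore accepts a
  predecessor only when the total length matches within tolerance *and*
  its distance from the source is strictly smaller in float — exactly the
  infinitesimal-δ semantics (no free hops), and it keeps the recursion
  cycle-free on zero-distance cores. Members of a zero-distance clique
  consequently receive identical closeness and eigenvector values (their
  rows are exchangeable), which the tests assert to 1e-12.
* **Spectral shift.** Power iteration runs on W + σI with σ = max row
  sum. The shift leaves eigenvectors untouched and makes all shifted
  eigenvalues nonnegative, so convergence is governed by the gap at the
  top of the spectrum rather than by large-magnitude negative eigenvalues
  (a near-bipartite graph would otherwise stall). λ is recovered as the
  Rayleigh quotient with W itself.
* **Disconnected graphs** (thresholded views): the leading eigenvalue of
  a disconnected nonnegative matrix is not unique, so eigenvector
  centrality warns and computes per component, then renormalizes the full
  vector; closeness and betweenness are per-component by construction.
  Singleton components get eigenvector weight 1 before global
  renormalization and closeness 0.

**Thresholded graphs** keep edges with d ≤ t (nodes always retained) and
recompute centralities on the thresholded graph — matching the visual
semantics of a thresholded view, where the displayed colors describe the
displayed graph. A `recompute="pre"` flag attaches full-network
centralities instead, since the alternative reading is defensible.
Default thresholds for family views are 1e-20, 1e-50, 1e-80, 1e-100. The
**MST centrality graph** computes the same measures on the spanning tree
itself, so tree leaves have betweenness 0 and hub sequences stand out.

Because exported formats carry no arrowheads, cluster-diagram semantics
are encoded in an edge `role` attribute: `core-shortest` (zero-distance
edge inside a core), `toward-core` (tree edge in a cluster that has a
core), `tree`, `plain`.

## Membership classification

A query is a member iff d_min < τ, strictly; τ defaults to 0.0009, the
threshold that maximizes the F-measure of superfamily identification on
the reference dataset. Equality falls to non-member: the published
decision rule writes the strict inequality for the positive branch and
leaves equality unaddressed, so the conservative branch takes it. The
assigned cluster is that of the nearest base sequence (distance ties on
the minimum break to the smallest base id).

Non-members are optionally re-examined through a **remote-homology
provider** — any callable returning a remote-distance vector, typically
backed by an iterative profile search with 10 iterations or by a
precomputed table. d′_min < τ sets `remotely_related` without changing
the verdict: a remotely related sequence is still counted as outside the
family, mirroring how the reference evaluation scores such cases as
negatives. A provider failure is recorded on the result (attempted, error
note, `remotely_related=False`) rather than raised, so batch runs
survive a flaky external engine.

**Evaluation.** ROC uses score = −d_min; AUC is trapezoidal, which equals
the Mann–Whitney pair-counting statistic with half credit for ties
(property-tested against an independent pair-counting oracle). The
F-measure sweep evaluates F1 = 2PR/(P+R) at candidate thresholds placed
at geometric means of consecutive distinct distances — E-values are
log-scale, an arithmetic midpoint would be dominated by the larger value
— plus one candidate a decade above the maximum (the all-member
prediction). A zero-valued lower neighbor would collapse the geometric
mean to 0, which predicts nothing under the strict inequality, so it is
replaced by half the upper neighbor. Ties on F go to the smallest
threshold. F-measure means F1 throughout; no β-weighting is implied
anywhere.

## Synthetic generators

`planted_cluster_matrix` plants a multi-level hierarchy: fine cluster
sizes, groupings per level, and one log10-distance range per depth
(strictly separated, deeper = smaller). Distances are drawn log-uniformly
within their level's range; an optional zero-core fraction gives the
first ⌈fraction·size⌉ members of each fine cluster exact-zero pairwise
distances. Because MSC links every unit to its nearest neighbor, a
planted cluster is recovered exactly only if its internal link graph is
connected; the generator guarantees that by hub-star structure — within
each cluster/group, distances to the designated hub (first unit) come
from the lower half of the range, all other internal pairs from the upper
half. Exact recovery additionally requires every planted cluster and
group to have at least 2 units; a singleton necessarily links outward and
merges early (the toolkit's tests and acceptance runs use sizes ≥ 2
throughout).

`planted_classification_set` draws positive minimum distances
log-uniformly over the six decades below `pos_max` (the open interval
(0, pos_max] has no finite log range, so a six-decade window is the
concrete choice) and negatives between `neg_min` and 10, with
`pos_max < neg_min` enforced. `random_evalue_table` draws one base log10
E-value per pair uniformly in [−100, 1] and jitters the two directions
apart by up to the requested number of decades; zero asymmetry yields an
exactly symmetric table.

What the generators do **not** emulate: real BLAST score statistics
(length- and composition-dependent), overlapping families, outlier
sequences, annotation errors, or cluster-size distributions of a real
superfamily. Passing the planted-recovery and margin-classifier checks
therefore demonstrates algorithmic correctness under separated scales,
not expected accuracy on a real proteome, where scales overlap and the
published headline numbers depend on the specific dataset and search
engine build.

## Problem sizes and determinism

The acceptance measurements use problem sizes where exhaustive oracles
are exact and quick: 200 random connected graphs of ≤ 6 nodes for the
centrality-vs-enumeration comparison, 100 matrices of ≤ 7 units for
spanning-tree enumeration (all C(21,6) candidate trees at n = 7), 50
planted hierarchies, and 20 margin-separated classifier sets of 100
queries each. These sizes are the package's own choice of desk-scale
verification; the algorithms themselves have no size-specific code paths.

Everything downstream of input parsing is deterministic: all tie-breaks
are lexicographic, all randomness lives in the seeded generators, and all
artifact serialization uses sorted keys and fixed float formatting —
rerunning the pipeline on identical inputs is byte-identical (logs go to
a side channel, never into data outputs).

## Known limitations

* MSC here is a faithful implementation of the nearest-neighbor-link
  recursion, not the original authors' code; on datasets where the two
  differ in detail the cluster census may differ.
* Betweenness is exact (O(n³)-ish with dense pair loops) and intended for
  the cluster/family-sized graphs this toolkit targets, not for
  networks of tens of thousands of sequences.
* The remote-homology engine is pluggable but not bundled; no alignment
  or search is performed by the package itself.
* Level-2/level-3 groupings are pure MSC output; the toolkit separately
  exposes annotation-majority family labels rather than guessing how to
  blend the two.
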