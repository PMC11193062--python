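# Methods

`cdepp` implements clustered divide-and-conquer metric-learning placement:
inserting aligned query sequences into a fixed backbone phylogeny, and
extending that phylogeny with the queries, when the backbone is too large to
train a single sequence embedder on. This note records the model, the
parameter choices, the numerical decisions, and what the synthetic
experiments do and do not demonstrate.

## The model

**Metric-learning embedders.** For a backbone tree T with patristic
distances d_ij and aligned sequences s_i, an embedder Φ maps a one-hot
encoded sequence to a point in R^d by minimizing

    L(Φ) = Σ_{i<j} (1/d_ij) · (‖Φ(s_i) − Φ(s_j)‖₂ − d_ij)²

so Euclidean distances in embedding space approximate tree distances. The
1/d_ij weight emphasizes close pairs, which matter most for placement.
Pairs with d_ij = 0 are excluded from the sum and counted as a diagnostic
(the simulator additionally removes duplicate sequences, so such pairs
should not arise in normal runs).

The network is deliberately small: one site-wise convolution (kernel width
1 over the 4 nucleotide channels), a residual block of two such
convolutions whose input is added to their output, and one fully connected
layer to R^d. Gap and ambiguity columns are encoded as all-zero vectors,
so they contribute only bias terms. The implementation is a compact numpy
module with hand-written backward passes and Adam; training is a
deterministic function of the seed.

**Divide and conquer.** The backbone is decomposed into first-level
clusters t₁…t_c, each the leaf set of a connected subtree with at most m
leaves, minimizing c. The greedy post-order sweep (close the largest child
clusters at a node until the remainder fits) is linear-time; its
optimality is not assumed but enforced by a test against an exact
Pareto-frontier dynamic program. Each cluster is augmented with the
k = ⌈m·ln(c)/3⌉ outside leaves nearest to it (minimum patristic distance
to any member, ties by label), giving overlapping training sets t̂ᵢ: the
overlap both regularizes the local experts and covers queries that fall
near cluster boundaries. One embedder is trained per t̂ᵢ on the patristic
submatrix of the full backbone.

**Two-level routing.** Each tᵢ is further split into second-level clusters
of at most m′ leaves. A classifier with the same trunk architecture and a
softmax head is trained (cross-entropy against the one-hot second-level
label) over all second-level clusters. At query time the first-level score
is the maximum probability among a cluster's second-level classes
(s_i = max_j p_j^i); up to 4 first-level clusters are used as long as each
score is at least 1/200 of the previously taken one. Small classes keep
the classifier honest about uncertainty — with large classes a single
confident-but-wrong vote can dominate, which matters when gene histories
disagree with the species tree (horizontal transfer).

**Placement.** Each selected cluster's embedder yields distances from the
query to that cluster's (augmented) members; overlapping estimates are
combined by the median, leaves outside every selected cluster stay
missing. Placement minimizes, per backbone edge (u parent, v child,
length l),

    Q(p, x) = Σ_observed w_i (d_i − d̂_i)²,
    d̂_i = p + x + dist(u, i)       (proximal leaves)
    d̂_i = p + (l − x) + dist(v, i) (distal leaves)

over pendant length p ≥ 0 and distal position x ∈ [0, l], with weights 1,
1/d, or 1/d² (default 1/d², the Fitch–Margoliash choice). The quadratic is
convex; the box-constrained optimum is obtained exactly by comparing the
interior stationary point with the re-optimized faces and corners. Ties in
Q* are broken toward the edge nearest the smallest observed distance, then
by edge id. Results are serialized as jplace v3 over an edge-numbered
Newick; edge identity is child-node identity and ids are stable under
grafting.

**Tree update.** Queries are assigned to the first-level cluster with the
highest score, averaged across genes when several genes are available. Per
cluster, a complete distance matrix over the cluster's *augmented* members
plus its queries is built: query-involved entries are medians across genes
of model estimates, backbone–backbone entries are pinned to backbone
patristic distances. The augmented (not bare) member set is used because
representatives exist precisely to bracket attachments near cluster
boundaries. The subtree is re-inferred by neighbor joining, optionally
followed by nearest-neighbor-interchange hill climbing on the balanced
minimum-evolution length (Pauplin's formula, Σ_{i<j} 2^{1−t_ij} d_ij) with
ordinary-least-squares branch lengths, negatives clamped to zero.

**Backbone-preserving merge.** Rather than handing the re-inferred
subtrees to an external supertree program, the merge grafts queries one at
a time (nearest to the backbone first) onto the growing full tree by the
same constrained least squares, using each query's path lengths *in its
updated subtree* to the members already present. Grafting only subdivides
edges and adds pendants, so the restriction of the result to backbone
leaves is topologically identical to the backbone by construction — a
checkable invariant. When residuals tie along a path (which happens
exactly when the reference leaves all lie on one side of the attachment),
the tied edges are filtered by a topological consistency test: attaching
the query at an edge makes it sibling to the present members below that
edge, and that split must be a bipartition of the updated subtree
restricted to the members placed so far. The distance data alone cannot
break these ties; the inferred topology can. An export of
(backbone + updated subtrees) as multi-tree Newick is provided for users
who prefer an external supertree merge.

A genuine limitation remains: if a query clade's true attachment lies
outside the span of its assigned cluster's augmented members, every point
along the outward path fits the within-cluster distances equally well, and
no merge rule can recover the exact position from that information. Larger
m (fewer, bigger clusters) and representative augmentation shrink the
frequency of such configurations; they vanish when a single cluster covers
the backbone.

## Parameters

| parameter | default | test profile | meaning |
|---|---|---|---|
| m | 1500 | 64 | max first-level cluster size (leaves) |
| m′ | 30 | 8 | max second-level cluster size |
| k | ⌈m·ln c/3⌉ | same | representatives per cluster (natural log) |
| d | 128 | 16 | embedding dimension |
| channels | 64 | 32 | trunk width |
| epochs | 2000 | 150 (embedder) / 400 (classifier) | Adam epochs |
| lr | 1e-4 | 1e-3 | Adam learning rate |
| batch | 32 | 32 | mini-batch size; loss uses within-batch pairs |
| max_models | 4 | 4 | routing cap |
| ratio | 1/200 | 1/200 | relative-score cutoff |
| weighting | fm (1/d²) | fm | least-squares weights (ols/be/fm) |

Whether k's logarithm is natural is not fixed by convention; ln is used
and exposed. The rounding of k is ⌈·⌉. The training schedule constants are
this package's defaults, not claims about any other implementation; the
test profile is sized so a full simulated study runs on one CPU core in
minutes, and the per-batch loss over within-batch pairs keeps memory at
O(batch²) instead of O(n²).

## The synthetic-data generator

The simulator emulates a prokaryote-style single-gene placement study:

- a birth–death species tree (default λ=1, μ=0.2) with n=256 extant tips;
  the process is run past the n-th speciation for one further exponential
  waiting time so tip edges are strictly positive;
- gene trees produced by random subtree-prune-regraft moves accepted until
  the normalized Robinson–Foulds distance to the species tree is within
  ±0.05 of a target (default 0.38) — a topology-level proxy for horizontal
  gene transfer that reproduces the discordance level directly rather than
  simulating explicit transfer events; branch lengths are carried over
  unchanged;
- indel-free sequences (default 400 bp) evolved site-i.i.d. under JC (or
  GTR via matrix exponentials), root state from the stationary
  distribution, so alignments are exact by construction;
- deduplication keeping one seeded-random representative per identical
  sequence group;
- queries: a 5% random leaf sample (placement experiments) or whole pruned
  clades of 5–10 leaves (update experiments), with each query's true
  attachment edge, distal position and pendant length recorded on the
  pruned backbone.

Everything is a pure function of the `SimConfig`, including the seed.

What passing tests on these data do **not** show: robustness to alignment
error (queries are aligned by construction), to gappy or fragmentary
sequences, to rate heterogeneity across sites or lineages, to explicit
transfer events with their length effects, or to backbone estimation
error. The generator's discordance is purely topological.

## Numerical choices and degenerate inputs

- Embedder/classifier arithmetic is float32; losses are accumulated in
  float64. Training snapshots the full-training-set loss periodically and
  returns the best parameters, so the recorded final loss never exceeds
  the initial one.
- Distances of exactly 0 in a profile are floored at 1e-8 inside the
  1/d and 1/d² weights.
- The per-edge solver enumerates interior + faces + corners of the (p, x)
  box; degenerate edges (all references on one side) fall out naturally
  via the face solutions.
- Residual ties use a tolerance of 1e-10 (relative to Q*).
- Saturated Jukes–Cantor distances (mismatch fraction ≥ 3/4) are +inf at
  the `jc_distance` level; update matrices cap them at twice the largest
  finite entry so distance methods stay finite.
- Zero-length branches are allowed everywhere; quartet topologies are
  decided on edge-count path lengths, with unresolved (tied) quartets
  treated as a distinct state.
- Quartet distance is exhaustive for n ≤ 30 and seeded uniform sampling
  above (default 100 000 quartets); exact algorithms for large n are out
  of scope.
- Unrooted (trifurcating-root) input to the decomposition is first rooted
  at the midpoint of the longest leaf-to-leaf path.

## Evaluation experiments

`cdepp.experiments` contains the seeded studies the test suite asserts on
and `scripts/acceptance.py` reports: exact-oracle checks of the partition
and the placement solver, loss/selection identities, simulator
calibration, the update round trip (two pruned 5–10-leaf clades on
64-leaf trees, rebuilt from exact distances; quartet distance to the
original < 0.01 with the backbone untouched), and a scaled end-to-end
study (n=256, nRF 0.38, 400 bp, 5% queries, three seeds) comparing the
clustered ensemble at m=64/m′=8/d=16 against a 64-leaf subsampling
baseline with the same training budget. Problem sizes were chosen so the
whole battery runs in minutes on one core; they are scaled-down study
conditions, not tuned quantities.

## Known limitations

- The classifier is trained per gene; multi-gene routing averages scores
  across genes rather than training a joint model.
- Placement reports a single best edge per query (like_weight_ratio 1); no
  placement uncertainty is computed.
- The APPLES-2-style "use only small distances" heuristic is available
  only as an optional nearest-leaves filter and is off by default.
- BME search is NNI-only; no subtree-prune-regraft moves during update
  inference.
- The merge fixes the backbone topology by construction; if the backbone
  is itself wrong near an attachment, the error is inherited.
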