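# Methods

This note records the models implemented in `netalign`, the choices made
where the underlying methods are published only qualitatively, and what
the synthetic benchmark does and does not demonstrate.

## Graphlet node cost function

The catalog enumerates every connected simple graph on 2–5 nodes up to
isomorphism by exhausting edge subsets and canonicalizing over node
permutations: 1, 2, 6 and 21 graphlets of sizes 2–5 (30 total). Each
graphlet's nodes are partitioned into automorphism orbits (1, 3, 11 and
58 per size class; 73 total). Graphlets are ordered by node count, then
edge count, then canonical adjacency; orbits are numbered along that
order and, within a graphlet, by ascending degree — which pins the
conventional low indices (orbit 0 = edge end, 1/2 = path end/middle,
3 = triangle) and the size-class boundaries 0 | 1–3 | 4–14 | 15–72.
Orbit numbering deeper inside a size class is this package's canonical
order; other implementations may permute orbits within a class, so GDV
columns are comparable across tools only up to that permutation.

The GDV of a node counts, per orbit, the connected induced subgraphs
touching it. Counting enumerates every connected induced subgraph once
(ESU-style recursive extension) and classifies occurrences through a
cached canonical-form lookup; the brute-force oracle used in tests
(subset enumeration + explicit isomorphism) is an independent code path.

GDV similarity between count vectors u, v:

```
D_i = w_i * |log(u_i+1) − log(v_i+1)| / log(max(u_i, v_i) + 2)
sim  = 1 − Σ D_i / Σ w_i,      w_i = 1 − log(o_i)/log(K)
```

`o_i` is the number of distinct orbits the orbit-i representative
touches within its own graphlet (equivalently: the orbits reachable as
connected induced subgraphs of the graphlet through that node), derived
programmatically from the catalog, not hard-coded. This induced-
containment rule keeps every weight strictly positive at every
truncation; a non-induced containment rule would assign weight exactly 0
to the maximal-clique orbit of each truncation (its affect count would
equal K) and silently delete the densest orbit from the similarity.
Truncation to T1/T2/T3 keeps orbit ranges {0}, {0..3}, {0..14} and
recomputes weights with K = 1, 4, 15; at K = 1 the single orbit gets
weight 1 by convention (the formula is 0/0 there).

## Spectral node cost function

The published description of the spectral signature is qualitative, so
this module fixes the details explicitly (all exposed as parameters):

* closed r-balls at **every** level r = 1..k, not only radius k, so
  coarser neighborhoods are not washed out by the largest ball;
* eigenvalues of the normalized Laplacian (isolated vertex ⇒ eigenvalue
  0), binned into **B = 32** equal-width bins over [0, 2] (right-closed
  final bin), normalized to unit mass;
* distance = mean over levels of ½·L1 between level histograms — a
  metric bounded in [0, 1], 0 iff the histograms coincide.

Numerical choices: eigenvalues are snapped to 9 decimals before binning
so values mathematically on a bin edge (e.g. λ = 1 in bipartite balls)
bin identically under any node ordering, then clipped to [0, 2]. Balls
beyond 500 nodes fall back to binning the 250 smallest plus 250 largest
eigenvalues (sparse solver) with a logged warning; at the problem sizes
this package targets the dense path is essentially always taken.

The original spectral aligner returns only a subset of pairwise
distances depending on network size; this module always returns full
matrices (completion of partial tables and top-K sparsification live in
the blending module: missing distances are filled with the maximum
observed distance; `topk_sparsify` keeps the K largest similarities with
row-major tie-breaking).

## Blending

`cost = α·T + (1−α)·S` with T the topological similarity matrix and S
raw bit scores divided by their maximum over observed cross-network
pairs (unobserved pairs get S = 0 — no sequence evidence). α = 0.5 for
single runs, sweep grid {0.0, 0.1, …, 1.0}. Normalizing sequence scores
by the global maximum mirrors the divide-by-max scaling used for
topology scores; no e-value or log transform is applied.

## Alignment strategies

Both strategies share one seed-and-extend engine. Seeds are the
unaligned cross pair of maximal cost; around each aligned pair (u, v) a
bipartite graph connects unaligned neighbors x of u and y of v iff some
neighbor of x is already aligned to some neighbor of y, and an exact
maximum-weight matching (blossom; not forced to be perfect) accepts new
pairs onto the frontier. When the frontier stalls the engine re-seeds
with the next-best unaligned pair; since every re-seed aligns at least
one node, totality is guaranteed without a separate leftover phase. All
tie-breaking is lexicographic on (source, target) labels, and matchings
are built from sorted insertions, so identical inputs give identical
alignments.

The QAP-aware weight is `λ·cost(x,y) + (1−λ)·consistency(x,y)` with

```
consistency = 1 − mean over anchors (a, f(a)) of |W1(x,a) − W2(y,f(a))|
```

where the anchors are the already-aligned members of the closed
neighborhood of the pair being expanded and W1/W2 are the same NCF
evaluated within each network. This is a reconstruction: the published
QAP-based strategy is described only at the level of "uses within-network
distances in addition to cross-network ones", and its exact estimation
procedure is not recoverable from that description. The formulation here
preserves that distinguishing feature while being deterministic, and
reduces exactly (bit-for-bit) to the linear strategy at λ = 1. Default
λ = 0.5 weights the two information sources equally. The `M-G`
combination (graphlet NCF + QAP-aware AS), which the original tools
could not express, is supported by construction.

## Quality measures

The five topological measures follow the standard definitions (see the
README). For LCCS, the conserved-edge graph is built on the smaller
network's side; its connected components are identical on both sides
under an injective alignment, so the side is immaterial. The component
is chosen by most nodes, then most edges, then smallest label. E is the
LCCS edge count as a percentage of the minimum of the two induced edge
counts (on the component and on its image); if that minimum is 0 the
component is a single conserved edge's endpoints at most, and E is
reported 0. Degenerate cases are reported, not crashed on: ICS with an
edgeless image is 0 with an `ics_defined=False` flag, and GO/EXP with no
doubly-annotated pairs are `None`, never 0.

Measure correlations (Pearson/Spearman) drop undefined entries pairwise
and report constant measures as NaN rows/columns. The benchmark's
correlation analysis selects, per (pair, aligner), the report maximizing
a chosen measure (NC where truth exists, else EC) before correlating.

## Synthetic benchmark: what it emulates, and what not

`add_noise` adds `round(x/100·|E|)` uniformly sampled non-edges (or
edges from a user-supplied low-confidence pool) to a base network, for
x = 5..25 step 5 — the base is an exact subgraph of each variant and the
identity is the ground truth, as in the classic high-confidence-plus-
noise PPI benchmark. Real noise is not uniform: low-confidence
interactions concentrate around sticky proteins, so uniform noise is the
benchmark's idealization (`pool` restores the real protocol when such
data exists).

Because every deterministic tie-break is lexicographic, aligning a
network to a *same-labeled* noisy superset leaks the truth through label
equality. The α-study and recovery experiments therefore relabel the
noisy network with a random permutation (`relabel_network`), which is
the honest form of the benchmark; `NoiseSeries` itself keeps the
label-identity truth of the protocol it models.

The asymmetric fixture generator draws Erdős–Rényi graphs (default
n = 30, p = 0.15 — sparse, PPI-like average degree ≈ 4) until the
automorphism group is trivial; with `distinct_gdv` it additionally
requires all-distinct T4 GDVs, i.e. a fully topologically identifiable
instance, which is the premise of a ground-truth-recovery experiment.
Synthetic sequence scores draw one BLAST-like bit score per paralog
family (default family size 5) shared by all of the family's cross
pairs, so sequence alone underdetermines the mapping within families —
the ambiguity real bit scores exhibit across paralogs. Synthetic
annotations give true pairs a shared GO term at a configurable rate.
None of these generators reproduce degree-distribution, modularity or
annotation-bias properties of real PPI data; passing the suite shows the
algorithms are implemented correctly and behave as expected under
controlled conditions, not that any aligner ranking carries over to real
interactomes.

Rank aggregation uses competition ranking with ties sharing the better
rank; "best-alignment" scope maximizes each (pair, aligner, measure)
over α and T before ranking, per measure rather than globally.

## Problem sizes

The package targets desk-scale instances: GDV counting is practical to
a few thousand edges, the spectral NCF to balls of a few hundred nodes,
and the test and acceptance workloads use networks of 5–40 nodes
(50 graphs of ≤ 12 nodes for oracle equivalence, 30-node graphs for
recovery and α-sweep studies), which exercise every code path in
seconds. Wall-clock time is logged but never asserted on.

## Known limitations

* Graphlets beyond 5 nodes, directed/weighted graphs and multigraphs are
  out of scope; many-to-many and multi-network alignment are not
  supported.
* The QAP-aware strategy is a reconstruction (above), not a reimplementation
  of the original tool's estimator; no binary compatibility is attempted.
* GDV orbit order within a size class is canonical to this package.
* The spectral signature uses plain histograms, not kernel-smoothed
  spectral densities.
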