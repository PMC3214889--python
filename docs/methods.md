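# Methods

`ppicluster` implements an in-silico pipeline for proposing candidate
assembly factors of a protein complex from physical protein–protein
interaction (PPI) data.  The pipeline has four stages: assembly of a
seed-centered un-weighted network from interaction-database snapshots,
overlapping dense-subgraph detection by greedy cohesiveness growth,
disjoint dense-subgraph detection by k-core vertex weighting, and a
subtraction step that exposes weakly connected *residual* proteins
reaching the complex through designated *anchor* subunits.

## Network model

Proteins are nodes named by their standard (SGD-style, upper-case) gene
names; an identifier map carries UniProt accessions and ordered-locus
names onto them.  Edges are unordered pairs; self-interactions
(homodimers) are allowed.  Records flagged as genetic interactions are
discarded during parsing: genetic screens cover genes unevenly, and
keeping them would skew the network toward the screens' coverage.  The
number of records collapsed onto an edge and the set of source
databases are stored as provenance but never used as weights — edge
weighting would systematically favour the most-studied proteins.

Cluster statistics over a node set C with n nodes:

* `m_int` — edges with both endpoints in C (a self-loop counts once);
* `m_bnd` — edges with exactly one endpoint in C;
* **density** = `m_int / (n(n+1)/2)`.  The denominator counts pairs
  *with* repetition because self-interactions are admissible; a single
  node with a self-loop has density 1.
* **quality (cohesiveness)** = `m_int / (m_int + m_bnd)`, or 1 when C
  has no incident edges.

## Assembly (five steps)

Given two snapshots A and B and a seed list:

1. *list 1* — the level-1.5 neighborhood of the seeds in A: every
   record touching a seed plus every record whose two endpoints each
   interact directly with some seed.
2. identifier unification (alias → canonical, single-valued map;
   unmapped partners are dropped with a logged warning or raise,
   configurable).
3. *list 2* — all direct seed interactions in B; *list 3* — records of
   B joining proteins new to list 2 (absent from list 1's endpoints) to
   the non-seed endpoint proteins of list 1.  Joins among the new
   proteins themselves are not admitted: the step exists to situate the
   new proteins in the seeds' functional environment, not to grow a
   second neighborhood around them.
4. the three lists are merged; each unique pair becomes one edge with
   the union of its source tags.
5. the result is un-weighted.

Seeds absent from every snapshot (e.g. mitochondrially encoded proteins
missing from a screen) are reported, never silently dropped.

## Overlapping clustering (cohesiveness growth)

Growth starts from **every** node.  From the current group, all single
node additions (external neighbors) and removals (current members) are
evaluated and the best strictly-improving move is applied until a local
maximum is reached.  The growth objective is the penalized
cohesiveness

    q_p(C) = m_int / (m_int + m_bnd + penalty · |C|),

with `penalty = 2` by default (the published value).  The penalty
models edges missed by the experiments; operationally it is what stops
the greedy walk from vacuuming up low-degree pendant chains — under the
plain ratio (`penalty = 0`, available everywhere) *any* pendant
addition strictly improves the quality, and on sparse-background
networks the walk drifts away from dense modules, frequently discarding
its own seed.  Reported cluster *quality* is always the plain
cohesiveness ratio.

Groups smaller than `min_size` (3) or with density below `min_density`
(0.25) are discarded, as are groups whose one-sided Mann–Whitney
p-value exceeds `max_pvalue` (0.05).  The test compares, across member
nodes, the intra-cluster degree against the boundary degree; when both
samples have ≤ 10 values the p-value is exact — the permutation
distribution of the rank-sum is built by dynamic programming over
(items taken, rank total), which enumerates all label assignments and
handles ties exactly — otherwise the tie-corrected normal approximation
is used.  Surviving groups with match coefficient
`|A∩B|²/(|A||B|) ≥ overlap_threshold` (0.8) are merged iteratively to a
fixed point; each merged union is polished back to a local maximum of
the growth objective (a raw union of two distinct local maxima is
generally not one) and re-scored, but not re-filtered.

Determinism: seeds are processed in decreasing-degree order with
lexicographic tie-break; move ties prefer additions, then the
lexicographically smallest node; with `penalty = 0` quality comparisons
use exact rational arithmetic.  Re-running on the same network is
byte-identical.

## Disjoint clustering (k-core vertex weighting)

Each node is weighted by `k* × density(K)` where K is the highest-order
k-core (order `k*`) of the induced subgraph on the node's closed
neighborhood; nodes without a 2-core weigh 0.  Density here is the
simple-graph density `2m/(n(n−1))`; self-loops carry no
neighborhood-density information and are ignored throughout this stage.
Complexes are expanded breadth-first from the heaviest unassigned
seeds, including unassigned neighbors whose weight is at least
`(1 − vwp)` times the seed weight (`vwp = 0.2`), to at most `max_depth`
(100) hops.  The *haircut* (on by default) iteratively removes members
with fewer than two within-complex neighbors; if pruning disconnects
the set, the component containing the seed is kept.  Complexes smaller
than 3 nodes are suppressed, matching the pipeline-wide minimum.
Complexes are node-disjoint: an assigned node is never re-seeded or
re-included.

A consequence of the threshold being relative to the *seed's* weight:
two equal-density regions joined by an edge are **not** separated (the
bridge neighbor passes the threshold), so a dumbbell of two 5-cliques
comes back as one complex.  Separation requires a local-density
contrast between the regions — which is exactly the situation in the
pipeline's use case, where the two sub-complexes differ in size and
wiring.

## Recursive partitioning and candidate discovery

The tree starts at the full network.  At each node the overlapping
clustering runs on the induced subgraph; accepted clusters become
children, and recursion continues into every seed-containing child (a
flag restricts it to the seed-richest child only).  When the clustering
yields no accepted cluster, or its largest accepted cluster covers
≥ 95% of the input — a child nearly equal to its parent is not a
split — the branch is declared unsplittable into overlapping sub-graphs
and is split once with the disjoint detector, ending that branch.

For every disjoint split, the **residual** is the parent's members
minus the union of its children.  Residual proteins with at least one
edge to an anchor are the candidates, ranked by anchor-edge count, then
seed-edge count, then name; seed proteins are annotated and ranked
last.  Anchors default to the seeds of the seed-poorest seed-containing
child: when a complex's subunits split between two dense sub-complexes,
the few subunits pulled into the "other" sub-complex are the natural
attachment points of the residual.  The *primary* report is the one
proposing the most non-seed candidates — a report whose candidates are
all known subunits is a null discovery; final triage of candidates by
annotation (e.g. preferring proteins of unknown function) is
deliberately out of computational scope and surfaced as an annotation
column instead.

## Synthetic data

The generator plants: dense modules (Bernoulli `intra_p` subgraphs,
optionally sharing nodes), Bernoulli `inter_p` cross-module edges, a
sparse background (`background_p`), designated anchor nodes inside one
module, and satellites attached to `satellite_degree` distinct anchors
and nowhere else.  Background random edges exclude the anchors: an
anchor-adjacent low-degree protein *is* the discovery target by
definition, so wiring background nodes to anchors would make the ground
truth mislabel its own candidates.  Everything is a pure function of
the RNG seed.

The fixed discovery scenario mirrors the discovery topology: module A
(17 proteins, 2 anchors), module B (8 proteins), `intra_p = 0.85`,
`inter_p = 0.15` between them, 5 satellites with 2 anchor edges each,
and 60 background proteins at 0.02; the seed list is module B plus the
anchors (10 proteins).

What the generator does **not** emulate: the heavy-tailed degree
distribution of real interactomes, study bias (hub proteins with
thousands of reported partners), correlated false positives from
shared experimental batches, and weighted evidence.  Passing tests
therefore demonstrate the pipeline's logic on clean planted structure,
not its robustness to real-database artifacts.

## Numerical and design choices

* Identifier comparison is case-sensitive; canonical names are
  upper-cased on ingestion (SGD convention).
* Exact-p-value cutoff: both samples ≤ 10 values (the exact DP is
  O(n² · rank-total) and instantaneous there).
* Degenerate significance inputs: a singleton group returns p = 1 with
  a warning; a zero-variance large sample returns 0.5.
* Coverage stop for "cannot split further": 95%.
* The local-maximality tolerance in verification is 1e-12; growth
  comparisons at `penalty = 0` are exact fractions.
* Problem sizes in the test-suite replicate studies (50 replicates,
  10–40-node graphs, the 90-node scenario) keep complete runs in
  seconds while leaving every code path exercised.

## Known limitations

* On a *closed* two-module graph (no background), the global maximum of
  cohesiveness is the whole graph (quality 1, no boundary).  With two
  size-10 modules sharing 2 nodes at `intra_p = 0.9`, greedy growth
  cascades into that union in roughly 13% of replicates (a module node
  with ≥ 3 edges across the shared pair and few outside edges makes
  absorption strictly improving), so both modules are recovered at
  Jaccard ≥ 0.8 in about 86% of replicates — not more — under any
  penalty setting.  Embedding the modules in a background does not
  remove the effect.
* The disjoint detector cannot separate equal-density regions joined by
  an edge (see above).
* The residual of a disjoint split may contain parent-module proteins
  that the core extraction dropped; such proteins can carry anchor
  edges and then appear among candidates.  This mirrors the original
  use case, where the residual was larger than the anchor-connected
  candidate set and the final selection used annotations.
* Historical database-snapshot outputs (network sizes, cluster tables)
  are not reproducible without the original snapshots and are treated
  as documentation only.
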