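# Methods

## Signaling model and assumptions

The package models intracellular signal transduction as a unidirectional
flow across ordered cellular compartments: a signal is received by a
membrane-bound receptor (*ExtMem*, the aggregate of extracellular fluid and
cell membrane), propagates through protein–protein interactions in the
*Cytosol*, and terminates at a DNA-binding transcriptional regulator in the
*Nucleus*.  Consecutive proteins on a path may interact within a shared
compartment, or one of the pair may traverse between adjacent compartments;
flow never skips a compartment and never moves backwards.  These
assumptions exclude, by construction, nuclear-receptor-initiated signaling
and any pathway relying on compartments outside the configured chain —
the `CompartmentModel` accepts arbitrary compartment chains and transition
relations, provided transitions are memoryless (the score at a node depends
only on the previous node's state).

## Reconstruction

Reconstruction is the classic k-shortest-loopless-paths formulation: the
interactome is augmented with a super-source feeding every receptor and a
super-sink drained by every TR through weight-1 (zero-cost) edges, edge
weights are transformed to costs −ln w, and Yen's algorithm enumerates
simple paths in non-decreasing cost order.  A path's reconstruction score
is the product of its edge weights, equal to exp(−cost).

Determinism required two deliberate choices:

* **Tie order.** Both in the Dijkstra subroutine and in Yen's candidate
  heap, equal-cost alternatives are ordered lexicographically on the node
  sequence.  Because a lexicographically smaller equal-cost path can enter
  the candidate heap *after* a larger one has been accepted, enumeration
  continues past k until the candidate cost exceeds the k-th accepted cost
  by more than the tie tolerance; the collected list is then sorted by
  (cost, node sequence) and truncated at k.  Truncation at a tie-group
  boundary therefore always keeps the lexicographically smallest members,
  and runs are reproducible across platforms.
* **Cost arithmetic.** Path costs accumulate left-to-right along the full
  node sequence (the spur search is seeded with the root's running cost),
  so the same node sequence always yields a bit-identical cost regardless
  of where Yen's algorithm deviated.  Products of the same weights in
  different orders can still differ in the last ulp, which is why tie
  grouping uses an absolute tolerance of 1e−9 on the cost scale rather
  than exact equality.

## Localization scores, costs, and the filter

Per-protein compartment scores ℓ_v^c ∈ [0, 1] follow the ComPPI convention
(three evidence tiers — experimental, predicted, unknown — giving high,
medium, low scores).  A protein absent from the table scores 0 everywhere.
Costs are −log ℓ, with 0 ↦ +∞ represented as a true IEEE infinity (never a
large constant), so infeasible assignments propagate exactly and
infinite-cost paths sort after all finite ones deterministically.  The log
base (natural by default) rescales all costs uniformly and cannot change
any argmin; this base-invariance is property-tested.  When reading
ComPPI-style tables, ExtMem is the maximum of the extracellular-fluid and
cell-membrane columns: a protein reachable in either is a plausible signal
origin.

The filter keeps exactly the edges with a positive interaction score (the
probability the interaction occurs somewhere in the cell); a missing score
counts as zero.  Filtering is idempotent and never adds edges.

## The compartment dynamic program

For a path (v₁, …, v_m) the DP computes s(vⱼ, c), the optimal cost of the
prefix ending with vⱼ in compartment c, generated from the transition
relation: staying in c costs nothing extra; arriving from a predecessor
compartment a adds the cheaper of ℓ̄(vⱼ, a) (vⱼ visits a and traverses) and
ℓ̄(vⱼ₋₁, c) (vⱼ₋₁ traverses first) — a traversing protein pays both
compartments.  Base cases pin v₁ to the start compartment; the path score
is s(v_m, end).  Runtime is O(m·|C|²).  Two-node paths are always
infinite: no single transition spans the chain, which is why
single-interaction reconstructions are effectively excluded once any
finite-cost path shares their tie group.

Traceback ties (several optimal predecessor compartments) resolve toward
the earliest compartment in chain order, which keeps compartment
transitions as late as possible — proteins stay at the membrane longest.
This affects only the reported labels, never the score.  The test oracle is
an independent exhaustive enumeration over all valid labelings and, per
compartment change, both traversal choices.

Re-ranking sorts each tie group by ascending signaling cost, stably on the
original rank; group boundaries, between-group order, and every
reconstruction score are untouched.  "Higher signaling score" is
interpreted on the probability scale, i.e. lower summed −log cost.

## Color-coding comparator

The comparator searches for *colorful* paths: every node gets a uniform
random color in {1..l} and a path of l vertices is accepted only if all
colors are distinct, which guarantees simplicity; a fixed l-vertex path is
colorful with probability l!/l^l, so `required_trials(l, p)` converts a
target success probability into a coloring budget.  For one coloring the
search itself is exact: a dynamic program over (node, used-color subset,
compartment) states returns the cheapest compartment-valid colorful path of
exactly l vertices, with localization binarized as score > 0.  The
k-shortest hybrid plugs this search into Yen's spur scheme — each spur
completion must itself be colorful (root colors count as used) and
compartment-ordered, with a fresh coloring per trial and a capped budget
(default 100 trials per spur, path lengths 2–8).  Unlike the localization
re-ranking pipeline, this method has no second score for breaking ties;
equal-cost paths keep the order the search produced.  With small trial
budgets the search is Monte Carlo: a valid path can be missed, which is the
method's documented weakness, not a defect of the implementation.

## Evidence-based edge weighting

Edge confidences are built from evidence-type labels: for each type t, the
probability that t supports signaling-related interactions is estimated as
the additively smoothed ratio (pos_t + a)/(pos_t + neg_t + 2a) over a
positive edge set (both endpoints annotated to a signaling GO term;
default GO:0009966) and a seeded uniform sample of negatives at 10× the
positive count.  Pseudocount a = 1 by default; the published description of
this weighting leaves the smoothing and combination unspecified, so this
package fixes the simplest consistent choice: per-type frequency estimation
and noisy-OR combination w = 1 − ∏(1 − p_t), capped at a ceiling of 0.75 to
keep single edges from dominating shortest-path costs.  Duplicate edges
collapse to the maximum weight with the union of evidence labels; zero
weights are dropped (the −log transform is undefined there) and weights
above 1 are rejected.

## Evaluation

Global assessment orders each distinct interaction by the index of the
first path containing it, then computes cumulative precision/recall against
pathway positives and a seeded negative sample at 50× the positives; edges
in neither set are skipped.  F1 is the pointwise harmonic mean (0 when both
terms are 0).  Aggregation across pathways is micro: pathway-tagged edges
are pooled, ordered by first-appearance index with ties broken by pathway
name, and the recall denominator is the total positive count.  Ground-truth
matching is directional by default with an undirected option, since curated
pathway files may be undirected.

Path-local assessment (*PosFrac*) is the per-path fraction of positive
edges — every non-positive edge counts against the path, with no negative
subsampling — averaged over non-overlapping windows (default 100 paths;
the final partial window averages over its actual size).  Method
comparisons use the one-sided Mann-Whitney U test: exact enumeration when
both samples have ≤ 8 observations and no ties, otherwise the normal
approximation with tie and continuity corrections (both modes agree within
0.01 at the boundary, which is tested).  F1 series and PosFrac series can
both be fed to the test.

## Synthetic benchmark

The generator emulates the two statistical features that make
localization information matter, not the topology of any real interactome:

* a weight palette of three values covering ~71% of edges (frequencies
  0.40/0.20/0.11; the remainder uniform on (0.05, 0.75)), reproducing the
  coarse-weight regime in which most paths are tied;
* a planted pathway layered ExtMem → Cytosol → Nucleus (6 receptors, 12
  middle proteins, 5 TRs, dense wiring) whose edges are the positives,
  plus two decoy classes among the middle proteins (one third of them,
  split evenly): *order-violating* decoys localized at the membrane and in
  the nucleus but not the cytosol — every interaction on their paths
  shares a compartment, yet no labeling respects the flow order, so only
  the dynamic program can demote them — and *mislocalized* promiscuous
  hubs, nucleus-only proteins touching every receptor and TR, whose
  receptor edges share no compartment and are removed by the filter.

Interaction scores are derived from compartment overlap,
max_c min(ℓ_u^c, ℓ_v^c), mirroring how interaction-level scores arise from
localization in ComPPI; localization noise (default 0.1) adds a
medium/low-tier score in a wrong compartment with the given probability.
Background edges are Erdős–Rényi over the remaining ordered pairs.  The
planted wiring is deliberately dense so that the number of planted paths
is commensurate with the reconstruction size k, as curated pathway edge
counts are relative to the k used on real interactomes.

The recovery experiment compares full pipelines, as method comparisons are
done on real data: the baseline reconstructs k shortest paths on the raw
interactome; the localization-aware pipeline filters first and re-ranks
ties afterwards.  A pure re-ranking never changes the multiset of per-path
PosFrac values (it is a permutation), so any honest comparison of
orderings alone would be a null comparison of means; the filter is where
list composition — and therefore recovery — changes.

What passing these tests does *not* show: the generator has no realistic
degree distribution, no evidence-type structure beyond a single label, and
decoys are planted rather than emergent, so results quantify the method's
behavior under its own assumptions, not expected performance on any real
interactome.

## Problem sizes and defaults

Defaults follow the regimes the method targets: k = 20,000 paths for real
interactomes, PR negative ratio 50, PosFrac window 100, evidence negative
ratio 10, weight ceiling 0.75.  The test-suite and acceptance-script runs
use desk-scale instances chosen as the smallest sizes that still exhibit
every phenomenon of interest — 400-edge synthetic interactomes (10,000
edges for weight-distribution statistics), k = 100, window 10, 20 seeded
replicates, 1,000 random paths for the DP oracle and 200 random digraphs
for the path-enumeration oracle.

## Known limitations

* Yen's algorithm is exact but O(k·n·SP); for very large k on large
  graphs the tie-boundary completion can enumerate substantially more than
  k paths when the k-th tie group is huge.
* The DP scores each path independently; it never re-weights edges or
  couples compartment choices across paths sharing proteins.
* The color-coding hybrid's completeness depends on its trial budget;
  guarantees are probabilistic.
* Compartment models must be memoryless chains or DAG-like relations; a
  compartment revisited after leaving (e.g. nucleus → cytosol shuttling)
  cannot be expressed.
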