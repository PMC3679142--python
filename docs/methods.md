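# Methods

## Problem and model

Given an undirected PPI graph G(V, E) with a positive reliability weight
w_ij on each edge, a catalog of known complexes, and per-protein domain
multisets, decide for each interacting pair whether it forms a complex of
exactly two proteins. The model has three parts:

1. a seven-dimensional feature map φ(P_i, P_j) built from the focal weight,
   the neighbourhood weights, and the two proteins' domain counts;
2. an indicator kernel K_dc over protein sets based on exact
   domain-composition equivalence;
3. a class-weighted soft-margin SVM (C-SVC with per-class penalties C+, C−)
   on the combined kernel, evaluated by stratified 10-fold cross-validation.

### Feature map

Neighbours of a pair {i, j} are all vertices adjacent to i or j excluding
the pair itself, and the focal edge is excluded from every statistic. F1 is
w_ij; F2/F3 are the max/min neighbouring edge weight; F4 is the largest
min(w_ik, w_jk) over common neighbours k; F5 is the largest |w_ik − w_jk|
over common neighbours; F6/F7 are the max/min of the two proteins' total
domain counts (with multiplicity; an unannotated protein counts 0). When a
pair has no qualifying neighbour, F2–F5 default to 0 — the "no competing
interaction" limit, which is also the value most favourable to the
heterodimer class and therefore consistent with the design intuition that
weak neighbourhoods indicate heterodimers.

The exact functional form of F5 is a genuinely open design point: "maximum
of differences between the neighbouring weights" admits several readings.
The default is the common-neighbour form max_k |w_ik − w_jk| because the two
literal alternatives (F2 − F3, or w_ij − F3) are linear combinations of
F1–F3 and would add nothing under a linear kernel. Both alternatives remain
available through `f5_mode` (`range`, `inside_minus_min`).

The neighbour set for F2/F3 is the union neighbourhood (adjacent to i *or*
j), not the common neighbourhood; the common-neighbour restriction applies
only to F4/F5, which are defined through a shared partner k.

### Composition kernel

Protein equivalence is multiset equality of domain compositions; set
equivalence asks for a permutation matching the members pairwise. Because
the underlying relation is equality of canonical forms, set equivalence is
decided by comparing sorted tuples of per-protein canonical compositions —
O(n log n) instead of enumerating the symmetric group — and a brute-force
permutation search is kept in the test suite as the independent oracle.
K_dc is the indicator of this equivalence; its Gram is a permutation of a
block-diagonal matrix of ones over the equivalence classes, hence positive
semidefinite, and the Gram builder exploits the same bucketing to run in
O(N log N) for N examples.

Unannotated proteins: equivalence must stay reflexive, but letting every
unannotated protein match every other would manufacture a large spurious
class. The default therefore assigns each unannotated protein a
pseudo-domain derived from its own identifier (reflexive, never matching
another protein); the alternative `unannotated="empty"` treats all
unannotated proteins as mutually equivalent. The kernel machinery accepts
protein sets of any size n even though the pipeline only uses n = 2.

### Combined kernel and classifier

The default combination is convex, (1 − α)·⟨φx, φy⟩ + α·K_dc with
α ∈ [0, 1]: α is a mixing weight interpolating between features-only (α = 0)
and composition-only (α = 1), and convexity of two PSD kernels keeps the
result PSD. The additive form k + α·K_dc (α ≥ 0 a penalty-free "positive
constant" reading) is retained behind `KernelConfig(form="additive")`.

Features are min–max scaled to [0, 1] per feature, with the scaler fit on
training data only (constant columns map to 0; applied values are not
clipped). The SVM solves the usual soft-margin dual with box constraints
0 ≤ a_i ≤ C+ for positives and 0 ≤ a_i ≤ C− for negatives; the quadratic
program is delegated to scikit-learn's SVC with a precomputed Gram
(`C=1`, `class_weight={+1: C+, −1: C−}`), and the dual coefficients, bias
and decision function are re-exposed. A decision value of exactly 0 is
called +1 (documented tie rule). Degenerate precision or recall (zero
denominator) is defined as 0 and logged.

### Cross-validation protocol

Stratified 10-fold splits from a seed (stratification matters: tens of
positives over 10 folds would otherwise often leave folds without
positives). Scaling and fitting use training folds only; the reported
precision, recall and F are arithmetic means of the per-fold values (mean of
per-fold F, not F of pooled counts). The grid search cross-validates every
(α, C+, C−) triple; ties on F break by higher precision, then lower α, then
lower penalties. The linear-kernel contribution analysis requires α = 0,
computes primal weights w = Σ y_i a_i x_i, and ranks features by
|w_k · x̄_k| — weight times dataset mean of the scaled feature — which is one
defensible reading of "coefficients and averages of the feature values";
ranking by |w_k| alone would be the other.

## Dataset construction rules

Positives: catalogued size-2 complexes whose pair is a network edge and is
not a proper subset of any *other* complex (an identical member set under a
different name is not a *proper* subset and does not disqualify). Negatives:
pairs co-occurring in a complex of size > 2 whose interaction is a network
edge, deduplicated across complexes. Any pair that is itself a catalogued
size-2 complex is excluded from the negatives even when it failed the
positive filter — such nested heterodimers are removed from the dataset
entirely. Output order is lexicographic by pair so folds are reproducible.

Reader conventions: delimiters are auto-detected (tab, semicolon, comma,
whitespace fallback) with an override; duplicate network rows collapse to
the maximum weight (weights are reliabilities — the most confident record
wins, order-independently); rows whose weight field is non-numeric are
skipped as headers and counted; self-interaction rows are dropped and
counted. For an external WI-PHI-style CSV the reader assumes columns
(protein A, protein B, weight) in that order; any further columns are
ignored.

## Synthetic study conditions

The generator plants the structure the method assumes and nothing else:

* **40 heterodimers**, each one strong internal edge;
* **20 larger complexes** (size 3–6, uniform), fully dense with strong
  internal edges — their internal pairs are the hard negatives;
* **300 background proteins** and i.i.d. weak edges over all protein pairs
  with probability 0.01;
* log-normal weights — in-complex median 40 (σ_log 0.4), background median 8
  (σ_log 0.6). Log-normal matches the positive, right-skewed character of
  reliability scores formed by multiplying association indices and
  log-likelihood scores;
* **domain compositions** of 1–4 domains drawn from a 60-domain vocabulary;
  80% of heterodimers are grouped into composition classes of 4 that reuse
  an exact pair of compositions — the signal K_dc exploits;
* **bridged heterodimers**: with probability 0.2 *per composition class*,
  every heterodimer in the class also gains one strong shared partner
  inside a large complex. These positives acquire high F2/F4 and are
  genuinely ambiguous in feature space. Bridging is applied per class
  rather than per pair because proteins with identical domain architecture
  share interaction behaviour; it is also what makes the composition kernel
  informative rather than decorative, since an ambiguous positive's
  class-mates are then themselves near the margin.

Heterodimer and large-complex memberships are disjoint, so the rule-based
dataset builder provably recovers the planted labels; this identity is
asserted in tests and in the acceptance script. What the generator does
*not* emulate: overlapping complexes, missing interactions inside true
complexes, weight-dependent annotation bias, unannotated proteins, and the
long-tailed degree distribution of real interactomes. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
behaviour of the method (hard negatives handled, composition signal
exploited), not the absolute accuracy attainable on a real interactome.

With these conditions the 10-fold averaged F at α = 0.6, C+ = C− = 1 sits
above 0.9 across seeds while the α = 0 baseline is distinctly lower, and
equalising the two weight distributions (with denser background so
neighbourhood sizes also equalise) collapses F towards the no-signal
baseline — evidence that performance comes from the planted structure, not
from leakage.

## Numerical choices and degenerate inputs

* Gram symmetry is required within 1e-8 of the matrix scale; PSD is verified
  in tests via smallest eigenvalue ≥ −1e-8 (absolute for indicator Grams,
  relative to scale for combined Grams).
* Duplicate unordered edges collapse to max; self-loops are invalid
  everywhere.
* Empty neighbourhoods give F2–F5 = 0; empty test sets predict nothing;
  single-class training labels raise.
* Fold seeds, generator seeds and grid tie-breaks are all deterministic;
  repeated runs are bit-identical.
* Problem sizes used in the shipped experiments (a few hundred examples,
  Grams of a few hundred rows) keep every pipeline run in seconds; the
  implementation is O(N²) in examples only where the Gram itself is O(N²).

## Known limitations

* The F5 definition and the combination form are documented interpretations
  with alternatives exposed in configuration, not uniquely determined facts.
* `feature_contributions` is undefined for α > 0 (the indicator has no
  primal representation) and raises rather than approximating.
* The monotonicity of training recall in C+ holds only statistically;
  solver tolerance can produce small inversions, and the test suite treats
  it accordingly.
* No identifier mapping: protein IDs must already agree across the three
  input tables (case-sensitive).
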