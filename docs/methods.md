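# Methods

## Model

A protein's multi-layered feature architecture is the union of its
annotated feature instances, grouped into layers by annotation source.
Pfam and SMART hits are merged into a single `pfam_smart` layer by default
(both are profile-HMM annotations that frequently cover the same
footprint); merging changes only the layer assignment of an instance,
never its type identity or count. Coordinates are 1-based and inclusive,
the Pfam/InterProScan convention, and every parser normalizes to it.

Two same-layer instances conflict when they share more than `max_overlap`
residues (default 0: any shared residue). A *path* through a layer is
formalized as a maximal set of pairwise-compatible instances. Maximality
matters: it forbids degenerate readings that drop compatible instances,
so a conflict-free layer has exactly one path containing everything, and
at `max_overlap ≥` protein length every layer collapses to one path.
Whether paths are maximal sets or arbitrary start-to-end walks was a
genuinely open design point; the maximal-set semantics is asserted
package-wide and tested against a brute-force enumeration of all 2^n
instance subsets. Maximal sets are enumerated as maximal cliques of the
compatibility graph (via networkx); the test oracle never uses that
route.

## Scoring

FAS(S, O) = α·MS + (1−α)·PS with α = 0.7 by default; raising α emphasizes
feature presence/copy number, lowering it emphasizes positional
agreement. Decisions that the formulas leave open:

* **Midpoints are exact.** An instance's relative position is
  (start+end)/2 divided by the protein length, kept as a fraction
  (possibly half-integer numerator) — no rounding.
* **Types missing from the target contribute 0 to both MS and PS** (the
  positional minimum over an empty set is treated as distance 1). This
  keeps PS ≤ 1 and makes FAS exactly 0 when no type is shared.
* **Weights come from the reference path's type set only.** Extra target
  types carry no weight; this is the designed source of the score's
  asymmetry, which the screens exploit (a reference nested in a larger
  target scores 1, the reverse direction less).
* **Many-to-one positional matching.** When the reference has more copies
  of a type than the target, each reference instance still matches its
  nearest target instance, possibly the same one repeatedly; the copy
  number penalty is MS's job.
* **Abundance weights** are computed as ω_i ∝ 1/(f(o_i)+1) and normalized
  to sum 1. The printed form of the weighting formula carries a numerator
  Σ_l(f(o_l)+1) that is constant across types and cancels in the
  normalization; the tests verify the equivalence against a literal
  transcription that keeps the constant. A type absent from the count
  table gets o_i = 1 with a warning — the most conservative choice, since
  count 1 yields the maximal weight. Minimum-weight floors are applied
  iteratively: floored types are pinned at their minimum and the
  remaining mass is redistributed over the others in proportion to their
  unconstrained weights (iterated because redistribution can push another
  floored type below its minimum); floors must sum to below 1.
* **Empty reference architectures score 0 with an `empty_reference` flag**
  instead of raising, so proteome-scale runs survive unannotated
  proteins.

## Overlap resolution

The exhaustive search evaluates every combination of alternative paths —
the cross product over both proteins' layers of each layer's maximal
compatible sets — scores each assembled pair of realizations, and returns
the maximum (ties: lexicographically first, so results are bit-identical
across runs). Searching per layer in isolation would not be exact here,
because the weight normalization couples layers: the reference's type set,
and hence every type's weight, depends on the paths chosen in *all*
layers.

The priority heuristic bounds that exponential cost. Each layer is
traversed greedily left-to-right: at each junction (a group of mutually
conflicting instances) the instance with the largest weighted incremental
contribution against the other protein's full instance set wins.
Contributions use weights and copy numbers from the full unresolved
architectures — the final path is unknown mid-traversal, so this
bookkeeping is necessarily approximate, and the greedy result is only a
lower bound. To escape greedy traps, the traversal is repeated once per
feature type with ≥ 2 instances in a layer, giving that type precedence
at every junction; per-layer candidate sets (greedy + priority paths) are
combined across layers by cross product, and all candidate realization
pairs are scored exactly, the best winning. Candidate counts stay at
1 + #multi-instance types per layer, so total work grows linearly with
the number of alternative paths. Every candidate is a maximal compatible
set, i.e. one of the exhaustively enumerated realizations — hence
exhaustive ≥ priority ≥ greedy holds by construction, as does
exhaustive ≥ e-value baseline (that resolution is also a maximal set).
The heuristic is not guaranteed to beat the e-value baseline.

Mode selection: exhaustive while the path-combination count is at most
`priority_threshold` (default 500), heuristic above it; the count itself
is computed with early termination so highly redundant architectures are
detected cheaply.

The e-value baseline resolves each layer greedily by smallest e-value;
instances without e-values (SEG, fLPS, COILS, tmhmm) rank after all that
have one, with ties broken by (start, type_id) for determinism. The
unresolved baseline scores the complete instance sets directly.

## Synthetic data

Real architectures come from running a battery of annotation tools over a
proteome; this package consumes pre-computed annotations, and its
generator produces structurally comparable stand-ins for development and
testing. `random_architecture` places instances uniformly at random
(overlaps, and hence redundant layers, arise naturally at realistic
densities); `perturb` applies seeded feature-type loss, instance
duplication, Gaussian positional drift (midpoint shifted, width
preserved, clipped to the sequence) and redundant decoy annotation
(a same-layer copy of a real instance's footprint, ±2 residues, under a
fresh type id — guaranteeing a junction at `max_overlap` 0).

`random_pair` emulates a moderately diverged ortholog pair: both proteins
derive from one ancestral architecture of 7 instances over 5 types in 2
layers on a 300-residue protein; the target diverges with 15% type loss,
15% duplication, positional drift of 3% of the length; both sides gain
redundant decoys at rate 0.3 per instance. These rates were chosen once
as a plausible ortholog-divergence regime that exercises every code path
(shared and lost types, copy-number changes, junctions on both sides).

What the generator does *not* emulate: domain-grammar structure (real
repeat regions have tandem geometry, not uniform placement), correlated
e-values between alternative models of the same footprint, and the
long-tailed redundancy of extreme repeat proteins. Consequently the
synthetic suite is *harder* for the greedy heuristic than real
annotations are — decoys are independent random types, so junction
decisions are adversarial — and the fraction of pairs where the heuristic
lands within 0.1 of the optimum (≈ 0.87–0.92 across seeds) should be read
as a lower bound on its accuracy on real data, not an estimate of it.
Passing tests demonstrate correctness of the machinery and the designed
orderings, not annotation-tool-specific behaviour.

The fixture pair (`figure1_fixture`) is a deterministic construction of
the motivating situation: a shared C-terminal domain plus a repeat region
redundantly annotated by three alternative models in the reference, with
the lowest-e-value model absent from the target. It reproduces the
strategy ordering unresolved < e-value-resolved < score-maximized
(0.60 < 0.67 < 1.00 with uniform weights).

## Problem sizes and numerics

The test suite and the acceptance script work on seeded pairs filtered to
at most 2000 path combinations, the regime where the brute-force oracle
(2^n subset enumeration per layer, full cross product of realizations) is
itself tractable; the acceptance script uses 300 pairs, the acceptance
tests 500. Score comparisons against the oracle demand exact equality
(identical floating-point path through identical summation order); the
linearity identity FAS = α·MS + (1−α)·PS is checked to 1e-9; weight sums
to 1e-9. The CLI prints scores to 4 decimals, enough to distinguish
scores at the granularity at which they are interpreted, and its outputs
are byte-identical across reruns.

## Limitations

* The greedy partial-score bookkeeping is one reasonable realization of
  an underspecified idea; other bookkeeping (e.g. recomputing weights
  from not-yet-visited instance counts during traversal) could reproduce
  different heuristic trajectories. The dominance chain and the final
  exact rescoring of candidates are invariant to that choice.
* Architecture complexity modulates score sensitivity: losing one type
  from a 10-type architecture moves FAS far less than from a 2-type one.
  Per-type minimum weights ameliorate this; calibrated per-protein score
  cutoffs are out of scope.
* No significance calibration: FAS is a similarity, not a p-value.
* Annotation execution (hmmscan, tmhmm, SEG, fLPS, COILS) is out of
  scope; the package consumes pre-computed annotations as JSON or
  InterProScan TSV.
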