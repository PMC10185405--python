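# archsim — multi-layered protein feature-architecture comparison

`archsim` scores the similarity of two proteins at the level of their
*feature architectures*: the ordered set of annotated features — Pfam/SMART
domains, transmembrane segments, low-complexity regions, coiled coils —
laid out along each sequence, with each annotation source forming one
*layer*. It is aimed at comparative genomics workflows that need a
quantitative, automatable stand-in for the visual comparison of domain
architectures: benchmarking ortholog assignments, screening ortholog pairs
for functional divergence, and spotting gene-model artefacts as
implausible architecture changes between proteome versions.

The hard part of architecture comparison is *redundancy*: several models
(e.g. alternative Pfam repeat families and the corresponding SMART model)
often annotate overlapping footprints in the same layer, so several
mutually exclusive readings of the architecture exist. `archsim`
represents each layer's instances as a compatibility graph — two instances
conflict when they share more than `max_overlap` residues — and resolves
overlaps *during* the comparison, by choosing for each protein the
non-redundant reading (one maximal compatible instance set per layer) that
maximizes the pairwise score. This avoids the classical failure mode of
picking the lowest-e-value annotation per footprint up front, which can
select different models in the two proteins and fabricate a signal of
architecture divergence.

## The score

For a reference protein S compared against a target O:

    FAS(S, O) = α · MS(S, O) + (1 − α) · PS(S, O),        α = 0.7 by default

with, summing over the feature types i annotated in (the resolved reading
of) S, each carrying weight ω_i with Σ ω_i = 1:

    MS(S, O) = Σ_i  ω_i · min( N_i^S · N_i^O / (N_i^S)² , 1 )

    PS(S, O) = Σ_i  (ω_i / N_i^S) · Σ_j ( 1 − min_l | P_{i,j}^S − P_{i,l}^O | )

Here N_i^S and N_i^O are the instance counts of type i in reference and
target, and P_{i,j} is the relative position of instance j — its interval
midpoint divided by the protein length. MS captures how completely the
reference's types and copy numbers recur in the target; PS captures how
well the shared types agree in relative position. Both lie in [0, 1]; the
score is asymmetric, reaching 1 when S is a positional sub-architecture of
O and 0 when no type is shared.

Weights are uniform (ω_i = 1/n) or abundance-driven: ω_i ∝ 1/(f(o_i)+1),
where o_i is the type's instance count in a reference proteome and f one
of ln, identity, log10, ⁴√, ⁸√ — rare types, less likely shared by chance,
weigh more. Per-type minimum weights can keep common but decisive types
(e.g. transmembrane segments) influential.

Overlap resolution searches the alternative readings for the pair that
maximizes FAS: exhaustively while the number of path combinations is at
most `priority_threshold` (default 500), otherwise with a linear-time
heuristic that traverses each layer greedily and once more per
multi-instance feature type with that type given priority at junctions.
Baselines for comparison: resolution by minimal e-value, and scoring the
unresolved architectures as-is.

## Worked example

`examples/overlap_resolution.py` builds a deterministic ortholog-like pair
whose reference carries a repeat region redundantly annotated by three
alternative repeat models, only one of which occurs in the target — and
the shared model is *not* the one with the best e-value:

```
path combinations to evaluate: 9
unresolved overlaps:   FAS = 0.5996
e-value resolution:    FAS = 0.6662
score maximization:    FAS = 0.9993
chosen reference path: pfam_smart/pfam:REP_A:10-40;pfam_smart/pfam:REP_A:50-80;...
```

Scoring the unresolved architectures dilutes the score with the two
non-shared repeat models (0.60); e-value minimization keeps the
best-scoring but unshared model and still misses the match (0.67); score
maximization recognizes that the two proteins share essentially the same
architecture (1.00). The other examples show pairwise scoring of
hand-built architectures (`score_pair.py`), the weighting schemes
(`weighting_schemes.py`), and the outlier screen over an ortholog group
(`ortholog_screen.py`).

## Command line

```sh
archsim ref.json tgt.json -o run --bidirectional --baselines
```

scores matched protein ids from two annotation JSON files (see the format
in `archsim.model.read_annotations`; an InterProScan 5 TSV adapter is
included) and writes a TSV with MS, PS, FAS, the search mode, the resolved
architectures, and optionally both score directions, the two baselines and
a phylogenetic-profile export (`--phyloprofile`, with `--taxa`). See
`archsim --help` for all flags (α, `--max-overlap`, weighting scheme,
`--min-weight TYPE=W`, `--priority-threshold`, pairing options).

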