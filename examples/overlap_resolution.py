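"""Compare the three overlap-resolution strategies on a redundant fixture.

The fixture mimics a repeat region annotated redundantly by three
alternative repeat models in the reference, where the model with the best
e-value is NOT the one shared with the target. Scoring the unresolved
architectures dilutes the score; resolving by minimal e-value picks the
wrong model; maximizing the score during comparison recovers the shared
sub-architecture.
"""

from archsim import (
    count_path_combinations,
    exhaustive_search,
    figure1_fixture,
    score_by_evalue,
    score_unresolved,
)

ref, tgt = figure1_fixture()
combos = count_path_combinations(ref, tgt, 0)
ex = exhaustive_search(ref, tgt)
ev = score_by_evalue(ref, tgt)
un = score_unresolved(ref, tgt)

print(f"path combinations to evaluate: {combos}")
print(f"unresolved overlaps:   FAS = {un.fas:.4f}")
print(f"e-value resolution:    FAS = {ev.fas:.4f}")
print(f"score maximization:    FAS = {ex.result.fas:.4f}")
print("chosen reference path:", ex.result.ref_path.describe())
print()
print("The ordering unresolved < e-value < score-maximized shows how both")
print("baselines underestimate the similarity of this ortholog-like pair.")
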