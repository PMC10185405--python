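"""Independent brute-force oracles for the test suite.

Everything here is deliberately naive: maximal compatible subsets come
from checking all 2^n index subsets, the best resolution from scoring the
full cross product of assembled realizations, and the score formulas from
a literal transcription of the published equations (including the
normalization constant that cancels). None of it shares code with the
package's search or enumeration paths.
"""

from __future__ import annotations

import math
from itertools import combinations, product

from archsim.graph import LayerPath, ResolvedArchitecture
from archsim.model import Architecture
from archsim.scoring import score_resolved_pair


def interval_overlap(a, b) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def brute_force_layer_paths(instances, max_overlap: int):
    """All maximal pairwise-compatible subsets, by 2^n enumeration."""
    n = len(instances)
    compatible_sets = []
    for r in range(n + 1):
        for subset in combinations(range(n), r):
            if all(
                interval_overlap(instances[i], instances[j]) <= max_overlap
                for i, j in combinations(subset, 2)
            ):
                compatible_sets.append(frozenset(subset))
    maximal = [
        s
        for s in compatible_sets
        if not any(s < t for t in compatible_sets)
    ]
    return sorted(sorted(s) for s in maximal)


def brute_force_realizations(arch: Architecture, max_overlap: int):
    layer_ids = sorted(arch.layers)
    per_layer = []
    for lid in layer_ids:
        insts = arch.instances(lid)
        subsets = brute_force_layer_paths(insts, max_overlap)
        per_layer.append([[insts[i] for i in idxs] for idxs in subsets])
    out = []
    for combo in product(*per_layer):
        paths = {
            lid: LayerPath(lid, list(sel)) for lid, sel in zip(layer_ids, combo)
        }
        out.append(ResolvedArchitecture(arch.protein_id, arch.length, paths))
    return out


def brute_force_best_fas(arch_s, arch_o, counts, params) -> float:
    """Maximum score over every assembled (reference, target) realization pair."""
    best = -1.0
    for ref in brute_force_realizations(arch_s, params.max_overlap):
        for tgt in brute_force_realizations(arch_o, params.max_overlap):
            best = max(best, score_resolved_pair(ref, tgt, counts, params).fas)
    return best


# --- literal transcriptions of the published score formulas -----------------

_LITERAL_TRANSFORMS = {
    "ln": math.log,
    "linear": lambda o: o,
    "log10": math.log10,
    "root4": lambda o: o ** 0.25,
    "root8": lambda o: o ** 0.125,
}


def literal_weights(abundances: dict[str, int], scheme: str = "ln") -> dict[str, float]:
    """w_i = p_i / sum_x p_x with p_i = [sum_l (f(o_l)+1)] / (f(o_i)+1).

    Keeps the constant numerator that cancels in the normalization, as the
    formula is printed.
    """
    f = _LITERAL_TRANSFORMS[scheme]
    numerator = sum(f(o) + 1.0 for o in abundances.values())
    p = {t: numerator / (f(o) + 1.0) for t, o in abundances.items()}
    total = sum(p.values())
    return {t: v / total for t, v in p.items()}


def literal_ms(ref_counts, tgt_counts, weights) -> float:
    total = 0.0
    for t, n_s in ref_counts.items():
        n_o = tgt_counts.get(t, 0)
        if n_o == 0:
            continue
        total += weights[t] * min(n_s * n_o / (n_s ** 2), 1.0)
    return total


def literal_ps(ref_midpoints, tgt_midpoints, weights) -> float:
    """ref_midpoints / tgt_midpoints: type -> list of relative midpoints."""
    total = 0.0
    for t, ps in ref_midpoints.items():
        qs = tgt_midpoints.get(t)
        if not qs:
            continue
        inner = sum(1.0 - min(abs(p - q) for q in qs) for p in ps)
        total += weights[t] / len(ps) * inner
    return total
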