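"""Score-maximizing overlap resolution.

Redundant annotation layers admit many non-redundant readings; the
representative architectures of a protein pair are the readings that
maximize the pairwise similarity score. Two strategies are provided:

* :func:`exhaustive_search` evaluates every combination of alternative
  paths through both architectures — exact, but the combination count
  grows as the product of per-layer path counts.
* :func:`priority_search` is a linear-time heuristic: a greedy traversal
  supplies a lower bound, and one additional traversal per multi-instance
  feature type gives that type precedence at every junction; the best
  scoring candidate pair wins.

:func:`compare` picks the exhaustive search while the combination count
stays at or below ``priority_threshold`` (default 500) and falls back to
the heuristic beyond it.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from itertools import product as _product_raw
from typing import Sequence

from .graph import (
    LayerGraph,
    LayerPath,
    ResolvedArchitecture,
    build_layer_graph,
    count_path_combinations,
    enumerate_resolved_architectures,
)
from .model import Architecture, FeatureCountTable, ScoringParams
from .scoring import (
    ScoreResult,
    compute_weights,
    score_resolved_pair,
)

EXHAUSTIVE = "exhaustive"
PRIORITY = "priority"


@dataclass
class SearchOutcome:
    result: ScoreResult
    combinations_evaluated: int
    mode: str


def exhaustive_search(
    arch_s: Architecture,
    arch_o: Architecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> SearchOutcome:
    """Evaluate all path combinations; return the maximum-scoring pair.

    Every resolved realization of the reference is scored against every
    realization of the target and the highest combined score is kept (ties
    resolve to the lexicographically first pair, so results are
    deterministic).
    """
    params = params or ScoringParams()
    refs = enumerate_resolved_architectures(arch_s, params.max_overlap)
    tgts = enumerate_resolved_architectures(arch_o, params.max_overlap)
    best: ScoreResult | None = None
    for ref in refs:
        for tgt in tgts:
            result = score_resolved_pair(ref, tgt, counts, params, mode=EXHAUSTIVE)
            if best is None or result.fas > best.fas:
                best = result
    assert best is not None
    return SearchOutcome(
        result=best, combinations_evaluated=len(refs) * len(tgts), mode=EXHAUSTIVE
    )


def _instance_contributions(
    arch: Architecture,
    other: Architecture,
    counts: FeatureCountTable | None,
    params: ScoringParams,
) -> dict[tuple, float]:
    """Per-instance weighted incremental score against the other protein.

    The greedy traversal needs a ranking of conflicting instances before
    the final path is known, so weights and copy numbers come from the
    full unresolved instance sets of both architectures. An instance of
    type t contributes its weighted share of the multiplicity term plus
    its own positional agreement with the nearest instance of t in the
    other protein (distance 1 when t is absent there).
    """
    type_ids = arch.type_ids()
    if not type_ids:
        return {}
    w = compute_weights(type_ids, counts, params)
    n_s = {t: 0 for t in type_ids}
    for inst in arch.instances():
        n_s[inst.type_id] += 1
    other_pos: dict[str, list[float]] = {}
    for inst in other.instances():
        other_pos.setdefault(inst.type_id, []).append(inst.midpoint / other.length)
    n_o = {t: len(v) for t, v in other_pos.items()}
    contrib: dict[tuple, float] = {}
    for inst in arch.instances():
        t = inst.type_id
        ns = n_s[t]
        no = n_o.get(t, 0)
        ms_term = min(ns * no / (ns * ns), 1.0) if no else 0.0
        pos = inst.midpoint / arch.length
        if t in other_pos:
            ps_term = 1.0 - min(abs(pos - q) for q in other_pos[t])
        else:
            ps_term = 0.0
        contrib[(inst.start, inst.end, t)] = (
            w[t] / ns * (params.alpha * ms_term + (1.0 - params.alpha) * ps_term)
        )
    return contrib


def _greedy_layer_path(
    g: LayerGraph,
    contrib: dict[tuple, float],
    priority_type: str | None = None,
) -> LayerPath:
    """One left-to-right traversal of a layer graph.

    At each junction (a group of mutually conflicting instances) the
    priority type wins if one of its instances is present; otherwise the
    instance with the largest partial-score contribution is taken. The
    result is always a maximal compatible set.
    """
    remaining = list(range(len(g.instances)))
    selected: list[int] = []
    while remaining:
        head = remaining[0]
        group = [head] + [
            i for i in remaining[1:] if not g.compatible(head, i)
        ]
        pool = group
        if priority_type is not None:
            prioritized = [
                i for i in group if g.instances[i].type_id == priority_type
            ]
            if prioritized:
                pool = prioritized
        chosen = max(
            pool,
            key=lambda i: (
                contrib.get(
                    (g.instances[i].start, g.instances[i].end, g.instances[i].type_id),
                    0.0,
                ),
                -i,  # ties: earliest instance in positional order
            ),
        )
        selected.append(chosen)
        remaining = [
            i for i in remaining if i != chosen and g.compatible(i, chosen)
        ]
    insts = sorted(
        (g.instances[i] for i in selected), key=lambda x: (x.start, x.end, x.type_id)
    )
    return LayerPath(g.layer_id, insts)


def _candidate_realizations(
    arch: Architecture,
    other: Architecture,
    counts: FeatureCountTable | None,
    params: ScoringParams,
) -> list[ResolvedArchitecture]:
    """Candidate non-redundant realizations for the priority heuristic.

    Per layer graph: the greedy path plus, for every feature type with at
    least two instances in the graph, the path where that type takes
    precedence at every junction. Layer candidate sets are combined across
    layers by cross product; each set has at most 1 + #multi-instance
    types members, so the total stays linear in the number of alternative
    paths.
    """
    contrib = _instance_contributions(arch, other, counts, params)
    layer_ids = sorted(arch.layers)
    per_layer: list[list[LayerPath]] = []
    for lid in layer_ids:
        g = build_layer_graph(arch, lid, params.max_overlap)
        paths = [_greedy_layer_path(g, contrib)]
        seen_paths = {
            tuple((i.start, i.end, i.type_id) for i in paths[0].selected)
        }
        if g.is_redundant:
            type_counts: dict[str, int] = {}
            for inst in g.instances:
                type_counts[inst.type_id] = type_counts.get(inst.type_id, 0) + 1
            for type_id in sorted(t for t, c in type_counts.items() if c >= 2):
                cand = _greedy_layer_path(g, contrib, priority_type=type_id)
                sig = tuple((i.start, i.end, i.type_id) for i in cand.selected)
                if sig not in seen_paths:
                    seen_paths.add(sig)
                    paths.append(cand)
        per_layer.append(paths)
    candidates: list[ResolvedArchitecture] = []
    for combo in _product_raw(*per_layer):
        candidates.append(
            ResolvedArchitecture(
                arch.protein_id, arch.length, dict(zip(layer_ids, combo))
            )
        )
    return candidates or [ResolvedArchitecture(arch.protein_id, arch.length, {})]


def arch_signature(resolved: ResolvedArchitecture) -> tuple:
    return tuple(
        (lid, tuple((i.start, i.end, i.type_id) for i in resolved.paths[lid].selected))
        for lid in sorted(resolved.paths)
    )


def greedy_lower_bound(
    arch_s: Architecture,
    arch_o: Architecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> ScoreResult:
    """Score of the purely greedy resolutions (the priority mode's lower bound)."""
    params = params or ScoringParams()
    ref = _candidate_realizations(arch_s, arch_o, counts, params)[0]
    tgt = _candidate_realizations(arch_o, arch_s, counts, params)[0]
    return score_resolved_pair(ref, tgt, counts, params, mode=PRIORITY)


def priority_search(
    arch_s: Architecture,
    arch_o: Architecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> SearchOutcome:
    """Heuristic search over greedy and per-type priority realizations.

    Candidate counts grow linearly with the number of multi-instance
    feature types, so the work stays linear in the number of alternative
    paths; for non-redundant architectures the single candidate pair
    equals the exhaustive result.
    """
    params = params or ScoringParams()
    refs = _candidate_realizations(arch_s, arch_o, counts, params)
    tgts = _candidate_realizations(arch_o, arch_s, counts, params)
    best: ScoreResult | None = None
    for ref in refs:
        for tgt in tgts:
            result = score_resolved_pair(ref, tgt, counts, params, mode=PRIORITY)
            if best is None or result.fas > best.fas:
                best = result
    assert best is not None
    return SearchOutcome(
        result=best, combinations_evaluated=len(refs) * len(tgts), mode=PRIORITY
    )


def compare(
    arch_s: Architecture,
    arch_o: Architecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> SearchOutcome:
    """Score a directed pair, choosing the search mode automatically.

    Exhaustive while the number of path combinations is at most
    ``params.priority_threshold``; the priority heuristic beyond that.
    """
    params = params or ScoringParams()
    combos = count_path_combinations(
        arch_s, arch_o, params.max_overlap, limit=params.priority_threshold
    )
    if combos <= params.priority_threshold:
        return exhaustive_search(arch_s, arch_o, counts, params)
    return priority_search(arch_s, arch_o, counts, params)


def bidirectional_mean(
    arch_a: Architecture,
    arch_b: Architecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> float:
    """Mean of the two directed scores; the symmetric summary used when
    neither protein is the natural reference."""
    fwd = compare(arch_a, arch_b, counts, params).result.fas
    rev = compare(arch_b, arch_a, counts, params).result.fas
    return (fwd + rev) / 2.0


def flag_outliers(group_scores: Sequence[float], candidate: float) -> bool:
    """Is a candidate score more than two standard deviations below the
    group mean?

    Uses the sample standard deviation (n-1 denominator); the inequality
    is strict, so a candidate exactly at mean - 2*SD is not flagged.
    """
    if len(group_scores) < 2:
        raise ValueError("need at least two group scores to estimate spread")
    mean = statistics.fmean(group_scores)
    sd = statistics.stdev(group_scores)
    return candidate < mean - 2.0 * sd
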