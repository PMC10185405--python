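"""Weighted similarity scoring of resolved feature architectures.

The similarity of a reference architecture S against a target O is the
linear combination

    FAS(S, O) = alpha * MS + (1 - alpha) * PS,        alpha = 0.7 by default

of the multiplicity score MS (how well the copy numbers of S's feature
types are represented in O) and the positional score PS (how well the
relative sequence positions of the shared types agree). Both range over
[0, 1]; the score is asymmetric — it reaches 1 when S resembles a
(sub-)architecture of O and 0 when the two share no feature type.

Feature-type weights either are uniform or decrease with a type's abundance
o_i in the reference proteome, w_i proportional to 1 / (f(o_i) + 1) with f
one of {ln, identity, log10, fourth root, eighth root}; weights always
normalize to sum 1 over the reference path's types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .graph import (
    LayerPath,
    ResolvedArchitecture,
    build_layer_graph,
    overlap_length,
    unresolved_realization,
)
from .model import Architecture, FeatureCountTable, FeatureInstance, ScoringParams

_WEIGHT_SUM_TOL = 1e-9

_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "ln": math.log,
    "linear": lambda o: o,
    "log10": math.log10,
    "root4": lambda o: o ** 0.25,
    "root8": lambda o: o ** 0.125,
}


@dataclass
class WeightVector:
    """Per-feature-type weights, strictly positive and summing to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.weights:
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"weights sum to {total}, expected 1")
            if any(w <= 0 for w in self.weights.values()):
                raise ValueError("weights must be positive")

    def __getitem__(self, type_id: str) -> float:
        return self.weights[type_id]


@dataclass
class ScoreResult:
    """Outcome of scoring one directed protein pair."""

    reference_id: str
    target_id: str
    ms: float
    ps: float
    fas: float
    alpha: float
    mode: str
    weights: WeightVector
    ref_path: ResolvedArchitecture | None = None
    tgt_path: ResolvedArchitecture | None = None
    empty_reference: bool = False


def compute_weights(
    type_ids: set[str] | frozenset[str],
    counts: FeatureCountTable | None,
    params: ScoringParams | None = None,
) -> WeightVector:
    """Weights for a set of feature types.

    Uniform weighting assigns 1/n to each of the n types. The
    abundance-driven schemes assign w_i proportional to 1/(f(o_i)+1) so
    that rarer types — less likely shared by chance — carry more weight;
    the proportionality constant drops out in the normalization to sum 1.

    ``params.min_weights`` imposes per-type floors (e.g. to keep common but
    functionally decisive types such as transmembrane domains influential):
    floored types keep at least their minimum and the remaining mass is
    spread over the others in proportion to their unconstrained weights.
    """
    params = params or ScoringParams()
    if not type_ids:
        raise ValueError("cannot compute weights for an empty type set")
    ordered = sorted(type_ids)
    scheme = params.effective_weighting(counts)
    if scheme == "uniform":
        raw = {t: 1.0 for t in ordered}
    else:
        if counts is None:
            raise ValueError(f"weighting {scheme!r} requires a feature count table")
        f = _TRANSFORMS[scheme]
        raw = {t: 1.0 / (f(counts.get(t)) + 1.0) for t in ordered}
    total = sum(raw.values())
    weights = {t: v / total for t, v in raw.items()}

    floors = {t: w for t, w in params.min_weights.items() if t in weights}
    if floors:
        weights = _apply_floors(weights, floors)
    return WeightVector(weights)


def _apply_floors(
    weights: dict[str, float], floors: dict[str, float]
) -> dict[str, float]:
    """Raise floored types to their minimum, renormalizing the rest.

    Iterates because redistributing mass can push a previously satisfied
    floor below its minimum.
    """
    if sum(floors.values()) >= 1.0 - _WEIGHT_SUM_TOL and len(floors) < len(weights):
        raise ValueError("minimum weights leave no mass for unfloored types")
    pinned: dict[str, float] = {}
    free = dict(weights)
    while True:
        newly_pinned = {
            t: floors[t] for t in list(free) if t in floors and free[t] < floors[t]
        }
        if not newly_pinned:
            break
        pinned.update(newly_pinned)
        for t in newly_pinned:
            del free[t]
        if not free:
            break
        mass = 1.0 - sum(pinned.values())
        if mass <= 0:
            raise ValueError("minimum weights exceed the available weight mass")
        free_total = sum(weights[t] for t in free)
        free = {t: mass * weights[t] / free_total for t in free}
    out = {**free, **pinned}
    total = sum(out.values())
    return {t: w / total for t, w in out.items()}


def _relative_midpoints(
    resolved: ResolvedArchitecture,
) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for type_id, insts in resolved.instances_by_type().items():
        out[type_id] = [inst.midpoint / resolved.length for inst in insts]
    return out


def multiplicity_score(
    ref: ResolvedArchitecture, tgt: ResolvedArchitecture, w: WeightVector
) -> float:
    """Weighted agreement of feature-type copy numbers.

    Each reference type i with N_S instances contributes
    w_i * min(N_S * N_O / N_S^2, 1); a type absent from the target
    contributes 0, and a target carrying at least as many copies as the
    reference saturates at the upper bound of 1.
    """
    ref_counts = {t: len(v) for t, v in ref.instances_by_type().items()}
    tgt_counts = {t: len(v) for t, v in tgt.instances_by_type().items()}
    score = 0.0
    for type_id, n_s in ref_counts.items():
        n_o = tgt_counts.get(type_id, 0)
        if n_o == 0:
            continue
        score += w[type_id] * min(n_s * n_o / (n_s * n_s), 1.0)
    return score


def positional_score(
    ref: ResolvedArchitecture, tgt: ResolvedArchitecture, w: WeightVector
) -> float:
    """Weighted agreement of relative instance positions.

    An instance's position is its midpoint (start+end)/2 divided by the
    protein length. Every reference instance of a shared type is matched to
    the nearest target instance of that type (many-to-one allowed) and
    contributes 1 minus that distance; types absent from the target
    contribute 0.
    """
    ref_pos = _relative_midpoints(ref)
    tgt_pos = _relative_midpoints(tgt)
    score = 0.0
    for type_id, positions in ref_pos.items():
        targets = tgt_pos.get(type_id)
        if not targets:
            continue
        inner = sum(
            1.0 - min(abs(p - q) for q in targets) for p in positions
        )
        score += w[type_id] / len(positions) * inner
    return score


def score_resolved_pair(
    ref: ResolvedArchitecture,
    tgt: ResolvedArchitecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
    mode: str = "fixed",
) -> ScoreResult:
    """Score one (reference realization, target realization) pair.

    Weights are computed over the reference realization's feature types
    only; extra target types carry no weight (the source of the score's
    asymmetry). An empty reference scores 0 and is flagged rather than
    raising, so pipelines survive unannotated proteins.
    """
    params = params or ScoringParams()
    ref_types = ref.type_ids()
    if not ref_types:
        return ScoreResult(
            reference_id=ref.protein_id,
            target_id=tgt.protein_id,
            ms=0.0,
            ps=0.0,
            fas=0.0,
            alpha=params.alpha,
            mode=mode,
            weights=WeightVector({}),
            ref_path=ref,
            tgt_path=tgt,
            empty_reference=True,
        )
    w = compute_weights(ref_types, counts, params)
    ms = multiplicity_score(ref, tgt, w)
    ps = positional_score(ref, tgt, w)
    return ScoreResult(
        reference_id=ref.protein_id,
        target_id=tgt.protein_id,
        ms=ms,
        ps=ps,
        fas=params.alpha * ms + (1.0 - params.alpha) * ps,
        alpha=params.alpha,
        mode=mode,
        weights=w,
        ref_path=ref,
        tgt_path=tgt,
    )


def fas_score(
    ref: ResolvedArchitecture,
    tgt: ResolvedArchitecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> ScoreResult:
    """FAS = alpha * MS + (1 - alpha) * PS for a fixed pair of realizations."""
    return score_resolved_pair(ref, tgt, counts, params)


def _evalue_rank(inst: FeatureInstance) -> tuple:
    # instances without an e-value rank after all that have one
    return (
        (0, inst.evalue) if inst.evalue is not None else (1, 0.0),
        inst.start,
        inst.type_id,
    )


def resolve_by_evalue(
    arch: Architecture, max_overlap: int = 0
) -> ResolvedArchitecture:
    """Overlap resolution by e-value minimization (the classical baseline).

    Per layer, greedily keep the remaining instance with the smallest
    e-value and discard everything incompatible with it. Instances without
    e-values (SEG, fLPS, COILS, tmhmm) rank after all instances that have
    one; ties break on (start, type_id). The result is a maximal
    compatible set, i.e. one of the layer's alternative paths.
    """
    paths: dict[str, LayerPath] = {}
    for layer_id in sorted(arch.layers):
        g = build_layer_graph(arch, layer_id, max_overlap)
        remaining = list(range(len(g.instances)))
        selected: list[int] = []
        while remaining:
            best = min(remaining, key=lambda i: _evalue_rank(g.instances[i]))
            selected.append(best)
            remaining = [
                i for i in remaining if i != best and g.compatible(i, best)
            ]
        selected_insts = sorted(
            (g.instances[i] for i in selected),
            key=lambda i: (i.start, i.end, i.type_id),
        )
        paths[layer_id] = LayerPath(layer_id, selected_insts)
    return ResolvedArchitecture(arch.protein_id, arch.length, paths)


def score_by_evalue(
    arch_s: Architecture,
    arch_o: Architecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> ScoreResult:
    """Baseline: resolve both architectures by e-value, then score."""
    params = params or ScoringParams()
    ref = resolve_by_evalue(arch_s, params.max_overlap)
    tgt = resolve_by_evalue(arch_o, params.max_overlap)
    result = score_resolved_pair(ref, tgt, counts, params, mode="baseline_evalue")
    return result


def score_unresolved(
    arch_s: Architecture,
    arch_o: Architecture,
    counts: FeatureCountTable | None = None,
    params: ScoringParams | None = None,
) -> ScoreResult:
    """Baseline: score the complete, possibly overlapping instance sets.

    Every layer's "path" is all of its instances. Redundant but agreeing
    annotations can buffer missing features and overestimate similarity,
    while disagreeing redundant annotations depress it.
    """
    params = params or ScoringParams()
    ref = unresolved_realization(arch_s)
    tgt = unresolved_realization(arch_o)
    result = score_resolved_pair(ref, tgt, counts, params, mode="baseline_unresolved")
    result.ref_path = None
    result.tgt_path = None
    return result


__all__ = [
    "WeightVector",
    "ScoreResult",
    "compute_weights",
    "multiplicity_score",
    "positional_score",
    "fas_score",
    "score_resolved_pair",
    "resolve_by_evalue",
    "score_by_evalue",
    "score_unresolved",
    "overlap_length",
]
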