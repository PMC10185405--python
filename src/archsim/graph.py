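"""Per-layer compatibility graphs and alternative-path enumeration.

Overlapping same-layer annotations make an architecture *redundant*: several
mutually exclusive readings of the layer exist. Each reading corresponds to
a path through the layer's instance graph, formalized here as a MAXIMAL set
of pairwise-compatible instances (two instances are compatible when they
share at most ``max_overlap`` residues). Maximality prevents degenerate
readings that drop compatible instances for no reason; instances from
different layers never conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx

from .model import Architecture, FeatureInstance


def overlap_length(a: FeatureInstance, b: FeatureInstance) -> int:
    """Number of residue positions shared by two instances.

    Intervals are closed, so [10, 20] vs [10, 20] overlap by 11 and
    [1, 50] vs [51, 80] by 0.
    """
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _instance_sort_key(inst: FeatureInstance) -> tuple:
    return (inst.start, inst.end, inst.type_id)


@dataclass
class LayerGraph:
    """Compatibility structure over one layer's instances.

    ``incompatible`` holds index pairs (i < j) of instances that overlap by
    more than the cut-off and therefore lie on alternative paths.
    """

    layer_id: str
    instances: list[FeatureInstance]
    max_overlap: int
    incompatible: set[tuple[int, int]] = field(default_factory=set)

    def compatible(self, i: int, j: int) -> bool:
        if i == j:
            return True
        a, b = min(i, j), max(i, j)
        return (a, b) not in self.incompatible

    @property
    def is_redundant(self) -> bool:
        return bool(self.incompatible)


@dataclass
class LayerPath:
    """One non-redundant reading of a layer: a maximal compatible set,
    ordered by position."""

    layer_id: str
    selected: list[FeatureInstance]

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for inst in self.selected:
            counts[inst.type_id] = counts.get(inst.type_id, 0) + 1
        return counts


@dataclass
class ResolvedArchitecture:
    """One non-redundant realization of an architecture: one path per layer.

    This is the unit that is scored; the *representative* architecture of a
    comparison is the resolved architecture whose path choice maximizes the
    pairwise similarity score.
    """

    protein_id: str
    length: int
    paths: dict[str, LayerPath]

    def instances_by_type(self) -> dict[str, list[FeatureInstance]]:
        out: dict[str, list[FeatureInstance]] = {}
        for layer_id in sorted(self.paths):
            for inst in self.paths[layer_id].selected:
                out.setdefault(inst.type_id, []).append(inst)
        for insts in out.values():
            insts.sort(key=_instance_sort_key)
        return out

    def type_ids(self) -> set[str]:
        return {inst.type_id for p in self.paths.values() for inst in p.selected}

    @property
    def n_instances(self) -> int:
        return sum(len(p.selected) for p in self.paths.values())

    def describe(self) -> str:
        """Compact text form: ``layer/type:start-end;...`` per instance."""
        parts = []
        for layer_id in sorted(self.paths):
            for inst in self.paths[layer_id].selected:
                parts.append(f"{layer_id}/{inst.type_id}:{inst.start}-{inst.end}")
        return ";".join(parts)


def build_layer_graph(
    arch: Architecture, layer_id: str, max_overlap: int = 0
) -> LayerGraph:
    """Build the compatibility graph of one layer.

    Two instances conflict iff they share more than ``max_overlap``
    residues; only instances of the same layer are considered.
    """
    if layer_id not in arch.layers:
        raise KeyError(f"{arch.protein_id}: no layer {layer_id!r}")
    instances = sorted(arch.instances(layer_id), key=_instance_sort_key)
    incompatible: set[tuple[int, int]] = set()
    for i in range(len(instances)):
        for j in range(i + 1, len(instances)):
            if instances[j].start > instances[i].end:  # sorted by start
                break
            if overlap_length(instances[i], instances[j]) > max_overlap:
                incompatible.add((i, j))
    return LayerGraph(layer_id, instances, max_overlap, incompatible)


def enumerate_layer_paths(g: LayerGraph) -> list[LayerPath]:
    """All maximal pairwise-compatible instance subsets of a layer.

    A layer with no internal conflicts yields exactly one path containing
    every instance. Output order is deterministic (lexicographic by
    selected instance indices).
    """
    n = len(g.instances)
    if n == 0:
        return [LayerPath(g.layer_id, [])]
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in g.incompatible:
                comp.add_edge(i, j)
    index_sets = sorted(sorted(c) for c in nx.find_cliques(comp))
    return [
        LayerPath(g.layer_id, [g.instances[i] for i in idxs]) for idxs in index_sets
    ]


def count_layer_paths(g: LayerGraph, limit: int | None = None) -> int:
    """Number of alternative paths through a layer.

    With ``limit`` set, counting stops at ``limit + 1`` so highly redundant
    layers (the exhaustive search scales exponentially with path count)
    can be detected without a full enumeration.
    """
    n = len(g.instances)
    if n == 0 or not g.incompatible:
        return 1
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in g.incompatible:
                comp.add_edge(i, j)
    count = 0
    for _ in nx.find_cliques(comp):
        count += 1
        if limit is not None and count > limit:
            return count
    return count


def count_path_combinations(
    arch_s: Architecture,
    arch_o: Architecture,
    max_overlap: int = 0,
    limit: int | None = None,
) -> int:
    """Number of (reference path, target path) combinations to evaluate.

    The product over all layers of both architectures of the per-layer path
    counts; capped just above ``limit`` when given.
    """
    total = 1
    for arch in (arch_s, arch_o):
        for layer_id in sorted(arch.layers):
            g = build_layer_graph(arch, layer_id, max_overlap)
            per_layer_cap = None
            if limit is not None:
                per_layer_cap = max(1, (limit // total) + 1)
            total *= count_layer_paths(g, limit=per_layer_cap)
            if limit is not None and total > limit:
                return total
    return total


def enumerate_resolved_architectures(
    arch: Architecture, max_overlap: int = 0
) -> list[ResolvedArchitecture]:
    """All non-redundant realizations of an architecture.

    The cross product over layers of each layer's alternative paths, in
    deterministic order. Intended for the exhaustive search and for small
    test fixtures; the count grows as the product of per-layer path counts.
    """
    layer_ids = sorted(arch.layers)
    per_layer = [
        enumerate_layer_paths(build_layer_graph(arch, lid, max_overlap))
        for lid in layer_ids
    ]
    out = []
    for combo in product(*per_layer):
        out.append(
            ResolvedArchitecture(
                arch.protein_id, arch.length, dict(zip(layer_ids, combo))
            )
        )
    return out or [ResolvedArchitecture(arch.protein_id, arch.length, {})]


def unresolved_realization(arch: Architecture) -> ResolvedArchitecture:
    """The architecture with every instance retained, overlaps and all.

    Not a valid path in redundant layers (instances may conflict); used by
    the unresolved-scoring baseline.
    """
    paths = {
        lid: LayerPath(lid, sorted(arch.instances(lid), key=_instance_sort_key))
        for lid in sorted(arch.layers)
    }
    return ResolvedArchitecture(arch.protein_id, arch.length, paths)
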