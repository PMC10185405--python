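"""Domain types and annotation I/O for multi-layered feature architectures.

A protein's *feature architecture* is the union of all annotated feature
instances across annotation sources. Each source (Pfam/SMART, transmembrane
prediction, low-complexity segments, coiled coils, ...) contributes one
*layer*; a layer holds *feature types* (e.g. a Pfam family), and each type
occurs as zero or more positioned *instances* on the sequence.

Coordinates are 1-based and inclusive at both ends, following the
Pfam/InterProScan convention. The native on-disk format is a small JSON
dialect (see :func:`read_annotations`); an adapter for InterProScan 5 TSV is
provided.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: Layer name that Pfam and SMART annotations are merged into. Both sources
#: are profile-HMM based and frequently annotate the same footprint, so by
#: default they form a single annotation layer.
MERGED_PFAM_SMART_LAYER = "pfam_smart"

#: Layers conventionally produced by the default annotation sources. The
#: vocabulary is open: any layer identifier is accepted.
DEFAULT_LAYERS = ("pfam_smart", "tmhmm", "seg", "flps", "coils")

WEIGHTING_SCHEMES = ("uniform", "ln", "linear", "log10", "root4", "root8")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class FeatureInstance:
    """One positioned occurrence of a feature type on a protein.

    Attributes
    ----------
    start, end
        1-based residue positions, both inclusive.
    evalue
        Annotation e-value where the source provides one (Pfam/SMART);
        ``None`` for sources without a significance measure (SEG, fLPS,
        COILS, tmhmm).
    """

    start: int
    end: int
    type_id: str
    layer_id: str
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}] for {self.type_id}"
            )
        if self.evalue is not None and self.evalue < 0:
            raise AnnotationError(f"negative e-value for {self.type_id}")

    @property
    def midpoint(self) -> float:
        """Exact interval midpoint, (start + end) / 2; may be half-integer."""
        return (self.start + self.end) / 2

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        ev = "" if self.evalue is None else f" e={self.evalue:g}"
        return f"{self.type_id}[{self.start},{self.end}]{ev}"


@dataclass
class Architecture:
    """A protein's multi-layered feature annotation.

    ``layers`` maps layer id -> type id -> list of instances sorted by
    (start, end). All instances must lie within ``[1, length]``.
    """

    protein_id: str
    length: int
    layers: dict[str, dict[str, list[FeatureInstance]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError(f"{self.protein_id}: non-positive length")
        for layer_id, types in self.layers.items():
            for type_id, insts in types.items():
                for inst in insts:
                    if inst.layer_id != layer_id:
                        raise AnnotationError(
                            f"{self.protein_id}: instance {inst} filed under "
                            f"layer {layer_id!r} but carries {inst.layer_id!r}"
                        )
                    if inst.type_id != type_id:
                        raise AnnotationError(
                            f"{self.protein_id}: instance {inst} filed under "
                            f"type {type_id!r}"
                        )
                    if inst.end > self.length:
                        raise AnnotationError(
                            f"{self.protein_id}: instance {inst} exceeds "
                            f"protein length {self.length}"
                        )
                types[type_id] = sorted(insts, key=lambda i: (i.start, i.end))

    def instances(self, layer_id: str | None = None) -> list[FeatureInstance]:
        """All instances, optionally restricted to one layer, in positional order."""
        layers = [layer_id] if layer_id is not None else sorted(self.layers)
        out: list[FeatureInstance] = []
        for lid in layers:
            for insts in self.layers.get(lid, {}).values():
                out.extend(insts)
        out.sort(key=lambda i: (i.start, i.end, i.type_id))
        return out

    def type_ids(self) -> set[str]:
        return {t for types in self.layers.values() for t in types}

    @property
    def n_instances(self) -> int:
        return sum(
            len(insts) for types in self.layers.values() for insts in types.values()
        )


@dataclass
class FeatureCountTable:
    """Per-type instance counts o_i in a reference proteome.

    Used by the abundance-driven weighting schemes: rarer feature types are
    less likely to be shared by chance and receive higher weight.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for type_id, count in self.counts.items():
            if count < 1:
                raise AnnotationError(
                    f"count table: non-positive count {count} for {type_id!r}"
                )

    def get(self, type_id: str) -> int:
        """Count for a type; missing types fall back to 1 (maximal weight)."""
        count = self.counts.get(type_id)
        if count is None:
            logger.warning(
                "feature type %r missing from count table; assuming count 1", type_id
            )
            return 1
        return count


@dataclass
class ScoringParams:
    """Tunable parameters of the architecture comparison.

    alpha
        Mixing weight of the multiplicity score against the positional
        score, FAS = alpha*MS + (1-alpha)*PS. Default 0.7.
    max_overlap
        Number of shared residues two same-layer instances may have before
        they are considered mutually exclusive. Default 0 (any shared
        residue creates redundancy).
    weighting
        "uniform" or one of the abundance transforms {ln, linear, log10,
        root4, root8}. ``None`` selects uniform without a count table and
        "ln" with one.
    min_weights
        Optional per-type weight floors in (0, 1]; their sum must stay
        below 1.
    priority_threshold
        Path-combination count above which the comparison switches from the
        exhaustive search to the linear-time priority heuristic. Default 500.
    merge_pfam_smart
        Place "pfam" and "smart" annotations in a single layer. Default True.
    """

    alpha: float = 0.7
    max_overlap: int = 0
    weighting: str | None = None
    min_weights: dict[str, float] = field(default_factory=dict)
    priority_threshold: int = 500
    merge_pfam_smart: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.max_overlap < 0:
            raise ValueError("max_overlap must be non-negative")
        if self.weighting is not None and self.weighting not in WEIGHTING_SCHEMES:
            raise ValueError(
                f"unknown weighting {self.weighting!r}; choose from {WEIGHTING_SCHEMES}"
            )
        if self.priority_threshold < 1:
            raise ValueError("priority_threshold must be positive")
        for type_id, w in self.min_weights.items():
            if not 0.0 < w <= 1.0:
                raise ValueError(f"min weight for {type_id!r} outside (0, 1]")
        if sum(self.min_weights.values()) >= 1.0:
            raise ValueError("minimum weights must sum to less than 1")

    def effective_weighting(self, counts: FeatureCountTable | None) -> str:
        if self.weighting is not None:
            return self.weighting
        return "uniform" if counts is None else "ln"


def _merge_layer_id(layer_id: str, merge: bool) -> str:
    if merge and layer_id in ("pfam", "smart"):
        return MERGED_PFAM_SMART_LAYER
    return layer_id


def _insert(
    layers: dict[str, dict[str, list[FeatureInstance]]], inst: FeatureInstance
) -> None:
    layers.setdefault(inst.layer_id, {}).setdefault(inst.type_id, []).append(inst)


def read_annotations(
    path: str, params: ScoringParams | None = None
) -> dict[str, Architecture]:
    """Read the native annotation JSON into Architectures.

    Format::

        {"proteins": {"<id>": {"length": int,
                               "features": {"<layer>": {"<type_id>":
                                   {"instances": [[start, end, evalue-or-null], ...]}}}}}}

    With ``params.merge_pfam_smart`` (the default) the layers ``"pfam"`` and
    ``"smart"`` are merged into ``"pfam_smart"``; instance counts are never
    changed by merging, only the layer assignment.
    """
    params = params or ScoringParams()
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: malformed JSON: {exc}") from exc
    proteins = doc.get("proteins")
    if not isinstance(proteins, dict):
        raise AnnotationError(f"{path}: missing top-level 'proteins' object")
    out: dict[str, Architecture] = {}
    for protein_id, record in proteins.items():
        if protein_id in out:
            raise AnnotationError(f"{path}: duplicate protein id {protein_id!r}")
        try:
            length = int(record["length"])
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(
                f"{path}: protein {protein_id!r}: missing or invalid 'length'"
            ) from exc
        layers: dict[str, dict[str, list[FeatureInstance]]] = {}
        for layer_id, types in record.get("features", {}).items():
            target_layer = _merge_layer_id(layer_id, params.merge_pfam_smart)
            for type_id, body in types.items():
                for row in body.get("instances", []):
                    if len(row) not in (2, 3):
                        raise AnnotationError(
                            f"{path}: protein {protein_id!r}, type {type_id!r}: "
                            f"instance record {row!r} must be [start, end, evalue?]"
                        )
                    start, end = int(row[0]), int(row[1])
                    evalue = None
                    if len(row) == 3 and row[2] is not None:
                        evalue = float(row[2])
                    try:
                        inst = FeatureInstance(
                            start=start,
                            end=end,
                            type_id=type_id,
                            layer_id=target_layer,
                            evalue=evalue,
                        )
                    except AnnotationError as exc:
                        raise AnnotationError(
                            f"{path}: protein {protein_id!r}: {exc}"
                        ) from exc
                    _insert(layers, inst)
        try:
            out[protein_id] = Architecture(protein_id, length, layers)
        except AnnotationError as exc:
            raise AnnotationError(f"{path}: {exc}") from exc
    return out


def write_annotations(architectures: Mapping[str, Architecture], path: str) -> None:
    """Write Architectures to the native JSON dialect (round-trips with
    :func:`read_annotations` at ``merge_pfam_smart=False``)."""
    doc: dict = {"proteins": {}}
    for protein_id, arch in architectures.items():
        features: dict = {}
        for layer_id in sorted(arch.layers):
            features[layer_id] = {}
            for type_id in sorted(arch.layers[layer_id]):
                features[layer_id][type_id] = {
                    "instances": [
                        [i.start, i.end, i.evalue]
                        for i in arch.layers[layer_id][type_id]
                    ]
                }
        doc["proteins"][protein_id] = {"length": arch.length, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


#: Default mapping of InterProScan analysis names to architecture layers.
DEFAULT_INTERPROSCAN_LAYER_MAP = {
    "Pfam": "pfam",
    "SMART": "smart",
    "TMHMM": "tmhmm",
    "SignalP": "signalp",
    "Coils": "coils",
    "SEG": "seg",
}


def read_interproscan_tsv(
    path: str,
    layer_map: Mapping[str, str] | None = None,
    params: ScoringParams | None = None,
) -> dict[str, Architecture]:
    """Adapt InterProScan 5 TSV output to Architectures.

    Expects the standard tab-separated layout with at least 11 columns:
    accession, md5, length, analysis, signature id, description, start,
    stop, score, status, date. Each row becomes one instance of type
    ``"<layer>:<signature>"`` in the layer designated by ``layer_map``;
    analyses without a mapping are skipped with a warning. The score column
    is taken as the e-value when numeric.
    """
    layer_map = dict(layer_map or DEFAULT_INTERPROSCAN_LAYER_MAP)
    params = params or ScoringParams()
    per_protein: dict[str, tuple[int, dict]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >=11 tab-separated columns, "
                    f"got {len(cols)}"
                )
            accession, _md5, length_s, analysis, signature = cols[:5]
            start_s, stop_s, score_s = cols[6], cols[7], cols[8]
            try:
                length = int(length_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-numeric protein length {length_s!r}"
                ) from exc
            if analysis not in layer_map:
                logger.warning(
                    "%s:%d: analysis %r has no layer mapping; row skipped",
                    path,
                    lineno,
                    analysis,
                )
                continue
            try:
                start, stop = int(start_s), int(stop_s)
            except ValueError:
                logger.warning(
                    "%s:%d: non-numeric coordinates (%r, %r); row rejected",
                    path,
                    lineno,
                    start_s,
                    stop_s,
                )
                continue
            try:
                evalue = float(score_s)
            except ValueError:
                evalue = None
            base_layer = layer_map[analysis]
            layer_id = _merge_layer_id(base_layer, params.merge_pfam_smart)
            inst = FeatureInstance(
                start=start,
                end=stop,
                type_id=f"{base_layer}:{signature}",
                layer_id=layer_id,
                evalue=evalue,
            )
            known_length, layers = per_protein.setdefault(accession, (length, {}))
            if known_length != length:
                raise AnnotationError(
                    f"{path}:{lineno}: conflicting lengths for {accession!r}"
                )
            _insert(layers, inst)
    return {
        pid: Architecture(pid, length, layers)
        for pid, (length, layers) in per_protein.items()
    }


def read_count_table(path: str) -> FeatureCountTable:
    """Read a 2-column TSV (type_id, count) of reference-proteome counts."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            type_id, count_s = parts
            if type_id in counts:
                raise AnnotationError(f"{path}:{lineno}: duplicate type {type_id!r}")
            try:
                count = int(count_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer count {count_s!r}"
                ) from exc
            if count < 1:
                raise AnnotationError(
                    f"{path}:{lineno}: count for {type_id!r} must be positive"
                )
            counts[type_id] = count
    return FeatureCountTable(counts)


def write_count_table(table: FeatureCountTable, path: str) -> None:
    with open(path, "w") as fh:
        for type_id in sorted(table.counts):
            fh.write(f"{type_id}\t{table.counts[type_id]}\n")


def count_features(architectures: Iterable[Architecture]) -> FeatureCountTable:
    """Tally instance counts per feature type over a proteome annotation.

    This derives the o_i abundances consumed by the abundance-driven
    weighting schemes from a set of annotated proteins.
    """
    counts: dict[str, int] = {}
    empty = True
    for arch in architectures:
        empty = False
        for types in arch.layers.values():
            for type_id, insts in types.items():
                counts[type_id] = counts.get(type_id, 0) + len(insts)
    if empty:
        raise AnnotationError("cannot count features over an empty proteome")
    if not counts:
        raise AnnotationError(
            "proteome contains no feature instances; abundance weights undefined"
        )
    return FeatureCountTable(counts)


def merge_pfam_smart(arch: Architecture) -> Architecture:
    """Re-file "pfam" and "smart" instances into the merged layer."""
    layers: dict[str, dict[str, list[FeatureInstance]]] = {}
    for layer_id, types in arch.layers.items():
        target = _merge_layer_id(layer_id, True)
        for insts in types.values():
            for inst in insts:
                _insert(layers, replace(inst, layer_id=target))
    return Architecture(arch.protein_id, arch.length, layers)
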