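"""Seeded generation of synthetic feature architectures.

Real multi-layered architectures are products of many annotation tools run
over a proteome; for development and testing this module generates
structurally comparable inputs: random architectures with naturally
occurring overlaps, seeded perturbations emulating the changes architecture
comparison is meant to detect (feature loss, duplication, positional
drift, redundant decoy annotation), and a deterministic two-protein fixture
mimicking the classic redundant tetratricopeptide-repeat situation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .model import Architecture, FeatureInstance


@dataclass
class PerturbationSpec:
    """Parameters of a seeded architecture edit.

    p_loss
        Probability of dropping a feature type entirely.
    p_dup
        Probability of duplicating an instance (shifted copy).
    shift_sd
        Standard deviation of positional shifts, as a fraction of the
        protein length; shifts move the midpoint and preserve the width.
    p_redundant
        Probability of adding an overlapping same-layer decoy instance
        under a fresh type id, guaranteeing a redundancy junction.
    """

    p_loss: float = 0.0
    p_dup: float = 0.0
    shift_sd: float = 0.0
    p_redundant: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_loss", "p_dup", "p_redundant"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.shift_sd < 0:
            raise ValueError("shift_sd must be non-negative")


def random_architecture(
    n_layers: int = 2,
    n_types: int = 4,
    n_instances: int = 6,
    length: int = 400,
    seed: int = 0,
    protein_id: str | None = None,
    with_evalues: bool = True,
) -> Architecture:
    """A reproducible random architecture.

    ``n_instances`` instances are drawn over ``n_types`` feature types
    spread across ``n_layers`` layers; positions are unconstrained, so
    same-layer overlaps (and hence redundant layers) arise naturally when
    the protein is densely annotated.
    """
    if n_layers < 1 or n_types < 1 or length < 1 or n_instances < 0:
        raise ValueError("generator parameters must be positive")
    rng = random.Random(seed)
    max_width = max(5, length // 4)
    if max_width > length:
        raise ValueError(f"cannot fit instances on a protein of length {length}")
    layer_of_type = {
        f"T{k}": f"L{k % n_layers}" for k in range(n_types)
    }
    layers: dict[str, dict[str, list[FeatureInstance]]] = {}
    for _ in range(n_instances):
        k = rng.randrange(n_types)
        type_id, layer_id = f"T{k}", layer_of_type[f"T{k}"]
        width = rng.randint(5, max_width)
        start = rng.randint(1, length - width + 1)
        evalue = 10 ** rng.uniform(-30, -2) if with_evalues else None
        inst = FeatureInstance(
            start=start,
            end=start + width - 1,
            type_id=type_id,
            layer_id=layer_id,
            evalue=evalue,
        )
        layers.setdefault(layer_id, {}).setdefault(type_id, []).append(inst)
    pid = protein_id or f"synthetic_{seed}"
    return Architecture(pid, length, layers)


def perturb(arch: Architecture, spec: PerturbationSpec) -> Architecture:
    """Seeded stochastic edit of an architecture.

    A pure function of ``(arch, spec)``: with all probabilities and
    ``shift_sd`` zero the output equals the input (modulo protein id
    suffix). Shifted instances keep their width; midpoints are clipped so
    the instance stays within ``[1, length]``.
    """
    rng = random.Random(spec.seed)
    layers: dict[str, dict[str, list[FeatureInstance]]] = {}
    decoy_serial = 0
    for layer_id in sorted(arch.layers):
        for type_id in sorted(arch.layers[layer_id]):
            insts = arch.layers[layer_id][type_id]
            if spec.p_loss > 0 and rng.random() < spec.p_loss:
                continue
            kept: list[FeatureInstance] = []
            for inst in insts:
                kept.append(_shift(inst, arch.length, spec.shift_sd, rng))
                if spec.p_dup > 0 and rng.random() < spec.p_dup:
                    kept.append(_shift(inst, arch.length, max(spec.shift_sd, 0.02), rng))
            layers.setdefault(layer_id, {}).setdefault(type_id, []).extend(kept)
            for inst in kept:
                if spec.p_redundant > 0 and rng.random() < spec.p_redundant:
                    decoy_serial += 1
                    jitter = rng.randint(-2, 2)
                    decoy = _clip(
                        inst.start + jitter,
                        inst.end - inst.start,
                        arch.length,
                    )
                    decoy_type = f"decoy{decoy_serial}"
                    layers.setdefault(layer_id, {}).setdefault(decoy_type, []).append(
                        FeatureInstance(
                            start=decoy[0],
                            end=decoy[1],
                            type_id=decoy_type,
                            layer_id=layer_id,
                            evalue=inst.evalue,
                        )
                    )
    return Architecture(f"{arch.protein_id}|perturbed", arch.length, layers)


def _clip(start: int, width_minus_1: int, length: int) -> tuple[int, int]:
    start = max(1, min(start, length - width_minus_1))
    return start, start + width_minus_1


def _shift(
    inst: FeatureInstance, length: int, shift_sd: float, rng: random.Random
) -> FeatureInstance:
    if shift_sd <= 0:
        return inst
    delta = round(rng.gauss(0.0, shift_sd * length))
    start, end = _clip(inst.start + delta, inst.end - inst.start, length)
    return replace(inst, start=start, end=end)


def random_pair(
    seed: int,
    n_layers: int = 2,
    n_types: int = 5,
    n_instances: int = 7,
    length: int = 300,
    divergence: PerturbationSpec | None = None,
    redundancy: float = 0.3,
) -> tuple[Architecture, Architecture]:
    """A seeded ortholog-like architecture pair.

    Both proteins derive from one random ancestral architecture. The
    reference gains redundant decoy annotations (probability
    ``redundancy`` per instance); the target additionally diverges —
    defaults emulate a moderately diverged ortholog: 15% feature-type
    loss, 15% instance duplication, positional drift of 3% of the protein
    length, and the same redundant-annotation rate.
    """
    base = random_architecture(
        n_layers=n_layers,
        n_types=n_types,
        n_instances=n_instances,
        length=length,
        seed=seed,
        protein_id=f"pair{seed}_ref",
    )
    ref = perturb(base, PerturbationSpec(p_redundant=redundancy, seed=2 * seed + 1))
    if divergence is None:
        divergence = PerturbationSpec(
            p_loss=0.15,
            p_dup=0.15,
            shift_sd=0.03,
            p_redundant=redundancy,
            seed=2 * seed + 2,
        )
    tgt = perturb(base, divergence)
    ref = Architecture(f"pair{seed}_ref", ref.length, ref.layers)
    tgt = Architecture(f"pair{seed}_tgt", tgt.length, tgt.layers)
    return ref, tgt


def figure1_fixture() -> tuple[Architecture, Architecture]:
    """A deterministic ortholog-like pair with a redundant repeat region.

    Mimics the classic situation of two peptidyl-prolyl-isomerase-like
    orthologs: both share a C-terminal catalytic domain and a low
    complexity segment, and the reference carries an N-terminal repeat
    region redundantly annotated by three alternative repeat models, only
    one of which also annotates the target. Constructed so that the three
    resolution strategies order strictly:

        unresolved  <  e-value resolution  <  score-maximized resolution

    because the lowest-e-value repeat model of the reference is NOT the
    model shared with the target.
    """

    def inst(type_id, layer, start, end, ev=None):
        return FeatureInstance(
            start=start, end=end, type_id=type_id, layer_id=layer, evalue=ev
        )

    ref_repeats = {
        # shared repeat model: modest e-values
        "pfam:REP_A": [
            inst("pfam:REP_A", "pfam_smart", 10, 40, 1e-5),
            inst("pfam:REP_A", "pfam_smart", 50, 80, 2e-5),
        ],
        # best e-values, but absent from the target
        "pfam:REP_B": [
            inst("pfam:REP_B", "pfam_smart", 12, 42, 1e-9),
            inst("pfam:REP_B", "pfam_smart", 52, 82, 5e-9),
        ],
        # weakest alternative annotation of the same footprints
        "smart:REP": [
            inst("smart:REP", "pfam_smart", 9, 41, 1e-3),
            inst("smart:REP", "pfam_smart", 49, 81, 2e-3),
        ],
    }
    ref = Architecture(
        "REF_PPIASE",
        370,
        {
            "pfam_smart": {
                **ref_repeats,
                "pfam:ISOMERASE": [
                    inst("pfam:ISOMERASE", "pfam_smart", 250, 370, 1e-50)
                ],
            },
            "seg": {"seg:lcr": [inst("seg:lcr", "seg", 130, 160)]},
        },
    )
    tgt = Architecture(
        "TGT_PPIASE",
        360,
        {
            "pfam_smart": {
                "pfam:REP_A": [
                    inst("pfam:REP_A", "pfam_smart", 10, 40, 1e-6),
                    inst("pfam:REP_A", "pfam_smart", 49, 79, 3e-6),
                ],
                "pfam:ISOMERASE": [
                    inst("pfam:ISOMERASE", "pfam_smart", 242, 358, 1e-45)
                ],
            },
            "seg": {"seg:lcr": [inst("seg:lcr", "seg", 126, 156)]},
        },
    )
    return ref, tgt
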