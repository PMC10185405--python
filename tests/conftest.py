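import sys
from pathlib import Path

import pytest

# make the shared brute-force oracles importable from every test module
sys.path.insert(0, str(Path(__file__).parent))

from archsim.model import Architecture, FeatureInstance


def make_instance(type_id, start, end, layer="L0", evalue=None):
    return FeatureInstance(
        start=start, end=end, type_id=type_id, layer_id=layer, evalue=evalue
    )


def make_architecture(protein_id, length, instances):
    layers = {}
    for inst in instances:
        layers.setdefault(inst.layer_id, {}).setdefault(inst.type_id, []).append(inst)
    return Architecture(protein_id, length, layers)


@pytest.fixture
def simple_pair():
    """Identical single-domain architectures on equal-length proteins."""
    ref = make_architecture("ref", 200, [make_instance("A", 50, 100)])
    tgt = make_architecture("tgt", 200, [make_instance("A", 50, 100)])
    return ref, tgt
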