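import pytest

from mnasar import (
    DescriptorSet,
    LabeledSet,
    ModelConfig,
    SynthConfig,
    make_descriptor_dataset,
    parse_structure,
    train,
)


@pytest.fixture(scope="session")
def planted_fixture():
    """Default planted-signal descriptor dataset (300 actives / 1200 inactives)."""
    return make_descriptor_dataset(SynthConfig())


@pytest.fixture(scope="session")
def planted_model(planted_fixture):
    features, labeled = planted_fixture
    return train([labeled], features)


@pytest.fixture
def toy_dataset():
    """Tiny hand-written descriptor dataset: 4 actives, 6 inactives, one unique descriptor.

    'enr' is enriched in actives; 'uniq' occurs in exactly one compound, so its
    removal under leave-one-out empties that descriptor's vocabulary slot.
    """
    feats = {
        "a1": DescriptorSet(frozenset({"enr", "bg1", "bg2"}), "a1"),
        "a2": DescriptorSet(frozenset({"enr", "bg2"}), "a2"),
        "a3": DescriptorSet(frozenset({"enr", "bg3", "uniq"}), "a3"),
        "a4": DescriptorSet(frozenset({"enr", "bg1"}), "a4"),
        "i1": DescriptorSet(frozenset({"bg1", "bg2"}), "i1"),
        "i2": DescriptorSet(frozenset({"bg2", "bg3"}), "i2"),
        "i3": DescriptorSet(frozenset({"bg1"}), "i3"),
        "i4": DescriptorSet(frozenset({"bg3"}), "i4"),
        "i5": DescriptorSet(frozenset({"enr", "bg1"}), "i5"),
        "i6": DescriptorSet(frozenset({"bg2"}), "i6"),
    }
    labeled = LabeledSet(
        activity_id="TOY",
        members=tuple((cid, cid.startswith("a")) for cid in sorted(feats)),
    )
    return feats, labeled


@pytest.fixture
def toy_config():
    return ModelConfig(min_actives=1)


@pytest.fixture
def water():
    return parse_structure("O", source_id="water")


@pytest.fixture
def methane():
    return parse_structure("C", source_id="methane")
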