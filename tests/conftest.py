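import pytest

from regulink import fixtures


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Default noisy study bundle (coverage 0.8, background 0.1), seed 1."""
    spec = fixtures.FixtureSpec(seed=1)
    return fixtures.generate(spec, tmp_path_factory.mktemp("noisy"))


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Noise-free bundle: full coverage, zero background binding."""
    spec = fixtures.FixtureSpec(
        seed=7,
        planted_regulators={
            0: fixtures.PlantedRegulator(0, "up", 1.0, "up"),
            1: fixtures.PlantedRegulator(0, "up", 1.0, "down"),
        },
        background_binding_prob=0.0,
    )
    return fixtures.generate(spec, tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def toy_ontology_text():
    return """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: middle
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
is_a: GO:0000002
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: mf leaf
namespace: molecular_function

[Term]
id: GO:0000009
name: gone
namespace: biological_process
is_obsolete: true

[Typedef]
id: part_of
name: part of
"""
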