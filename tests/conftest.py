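import pytest

from ontonorm import Ontology, SynthConfig, generate_ontology

CH3_OBO = """\
format-version: 1.2

[Term]
id: OBT:0001
name: habitat

[Term]
id: OBT:0002
name: soil
synonym: "dirt" EXACT []
is_a: OBT:0001

[Term]
id: OBT:0003
name: clay soil
is_a: OBT:0002
"""


def make_ontology(parents: dict, labels: dict | None = None) -> Ontology:
    concepts = frozenset(parents)
    return Ontology(
        concepts=concepts,
        labels=labels or {c: c for c in concepts},
        synonyms={c: [] for c in concepts},
        parents={c: frozenset(p) for c, p in parents.items()},
    )


@pytest.fixture
def ch3_path(tmp_path):
    p = tmp_path / "ch3.obo"
    p.write_text(CH3_OBO)
    return p


@pytest.fixture
def ch3():
    """Three-concept chain: 0003 is_a 0002 is_a 0001."""
    return make_ontology(
        {
            "OBT:0001": [],
            "OBT:0002": ["OBT:0001"],
            "OBT:0003": ["OBT:0002"],
        },
        labels={"OBT:0001": "habitat", "OBT:0002": "soil", "OBT:0003": "clay soil"},
    )


@pytest.fixture
def diamond():
    """R; A is_a R; B is_a R; C is_a A, is_a B."""
    return make_ontology({"R": [], "A": ["R"], "B": ["R"], "C": ["A", "B"]})


@pytest.fixture
def random_dag():
    def _make(n: int, seed: int, max_parents: int = 3) -> Ontology:
        return generate_ontology(
            SynthConfig(n_concepts=n, max_parents=max_parents, seed=seed)
        )

    return _make
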