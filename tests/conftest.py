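import random

import pytest

import plgrouper as pg


@pytest.fixture(scope="session")
def toy_dir():
    return pg.toy_fixture_dir()


@pytest.fixture(scope="session")
def toy_ontology(toy_dir):
    return pg.load_ontology(toy_dir / "ontology_edges.tsv", dialect="edge_list")


@pytest.fixture(scope="session")
def toy_groupers(toy_dir, toy_ontology):
    defs = pg.load_grouper_definitions(toy_dir / "groupers.yaml")
    return pg.compile_groupers(defs, toy_ontology)


@pytest.fixture(scope="session")
def toy_mapping(toy_dir):
    return pg.load_mapping(toy_dir / "mapping.tsv")


@pytest.fixture(scope="session")
def toy_entries(toy_dir):
    return pg.read_problem_list(toy_dir / "problems.csv")


@pytest.fixture
def diamond_ontology():
    """D -> {B, C}, B -> A, C -> A: the minimal polyhierarchy."""
    return pg.Ontology(
        [
            pg.Concept("A"),
            pg.Concept("B", parent_ids=frozenset({"A"})),
            pg.Concept("C", parent_ids=frozenset({"A"})),
            pg.Concept("D", parent_ids=frozenset({"B", "C"})),
        ]
    )


def make_random_dag(n_nodes: int, seed: int, max_parents: int = 3) -> pg.Ontology:
    """A random DAG: node i may only take parents among nodes < i."""
    rng = random.Random(seed)
    concepts = [pg.Concept("n0")]
    for i in range(1, n_nodes):
        k = rng.randint(0, min(max_parents, i))
        parents = frozenset(f"n{j}" for j in rng.sample(range(i), k))
        concepts.append(pg.Concept(f"n{i}", parent_ids=parents))
    return pg.Ontology(concepts)


def naive_ancestors(ontology: pg.Ontology, concept_id: str) -> set[str]:
    """Independent oracle: repeated parent expansion to fixpoint."""
    out: set[str] = set()
    frontier = set(ontology.concepts[concept_id].parent_ids)
    while frontier:
        out |= frontier
        frontier = {
            p for f in frontier for p in ontology.concepts[f].parent_ids
        } - out
    return out
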