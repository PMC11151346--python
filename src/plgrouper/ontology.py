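"""An is-a concept polyhierarchy with subsumption queries.

SNOMED CT (and terminologies shaped like it) arrange concepts in a directed
acyclic polyhierarchy: a concept may have several parents, and a concept
*subsumes* another when the second is the first or one of its transitive
descendants. Groupers are defined over this relation, so the only structure
needed here is the is-a skeleton — no description logic, roles or refsets.

Two on-disk dialects are supported:

``rf2_snapshot``
    SNOMED RF2 snapshot-style TSV pair: a concept file with at least ``id``
    and ``active`` columns, and a relationship file with ``sourceId``,
    ``destinationId``, ``typeId`` and ``active``, filtered to active is-a
    rows (``typeId`` 116680003).

``edge_list``
    A single TSV of ``child_id``, ``parent_id`` (and optional ``child_fsn``)
    rows. A row with an empty ``parent_id`` declares a concept (useful for
    naming roots) without adding an edge.

Inactive concepts are retained for audit but are excluded from traversal:
they have no edges in the query graph and looking them up raises
:class:`~plgrouper.errors.UnknownConceptError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import CycleError, DanglingParentError, OntologyError, UnknownConceptError

#: RF2 typeId of the is-a relationship.
ISA_TYPE_ID = "116680003"


@dataclass(frozen=True)
class Concept:
    """A single terminology concept.

    ``parent_ids`` lists the direct is-a parents; it never contains the
    concept's own id.
    """

    id: str
    fsn: str = ""
    active: bool = True
    parent_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("concept id must be nonempty")
        if self.id in self.parent_ids:
            raise OntologyError(f"concept {self.id!r} lists itself as a parent")


class Ontology:
    """A queryable is-a DAG over :class:`Concept` objects.

    The query graph contains only active concepts; its edges point from child
    to parent, so "ancestors of c" is graph reachability from c.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self._concepts:
                raise OntologyError(f"duplicate concept id {c.id!r}")
            self._concepts[c.id] = c
        if not self._concepts:
            raise OntologyError("ontology contains no concepts")

        g = nx.DiGraph()
        for c in self._concepts.values():
            if not c.active:
                continue
            g.add_node(c.id)
            for p in c.parent_ids:
                parent = self._concepts.get(p)
                if parent is None:
                    raise DanglingParentError(
                        f"concept {c.id!r} references unknown parent {p!r}"
                    )
                if parent.active:
                    g.add_edge(c.id, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise CycleError(
                f"is-a relation is cyclic; concept {cycle[0][0]!r} lies on a cycle"
            )
        self._g = g

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __getitem__(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(f"unknown concept {concept_id!r}") from None

    @property
    def concepts(self) -> Mapping[str, Concept]:
        return self._concepts

    @property
    def edge_count(self) -> int:
        """Number of traversable (active child → active parent) is-a edges."""
        return self._g.number_of_edges()

    @property
    def roots(self) -> frozenset[str]:
        """Active concepts with no active parent (a forest is permitted)."""
        return frozenset(n for n in self._g.nodes if self._g.out_degree(n) == 0)

    def is_active(self, concept_id: str) -> bool:
        return self[concept_id].active

    # -- queries ------------------------------------------------------------

    def _require_active(self, concept_id: str) -> None:
        if not self[concept_id].active:
            raise UnknownConceptError(f"concept {concept_id!r} is inactive")

    def ancestors(self, concept_id: str) -> set[str]:
        """Strict transitive ancestors of ``concept_id`` (self excluded)."""
        self._require_active(concept_id)
        return set(nx.descendants(self._g, concept_id))

    def descendants(self, concept_id: str) -> set[str]:
        """Strict transitive descendants of ``concept_id`` (self excluded)."""
        self._require_active(concept_id)
        return set(nx.ancestors(self._g, concept_id))

    def descendants_or_self(self, concept_id: str) -> set[str]:
        out = self.descendants(concept_id)
        out.add(concept_id)
        return out

    def subsumes(self, root_id: str, concept_id: str) -> bool:
        """True iff ``concept_id`` is ``root_id`` or a descendant of it."""
        self._require_active(root_id)
        self._require_active(concept_id)
        return root_id == concept_id or root_id in self.ancestors(concept_id)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise OntologyError(f"{path}: file is empty") from None
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise OntologyError(f"{path}: missing required column(s) {missing}")


def _load_edge_list(source: str | Path) -> Ontology:
    df = _read_tsv(source)
    _require_columns(df, ["child_id", "parent_id"], source)
    if df.empty:
        raise OntologyError(f"{source}: no rows")
    fsn: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        child = str(row.child_id).strip()
        parent = str(row.parent_id).strip()
        if not child:
            raise OntologyError(f"{source}: row with empty child_id")
        parents.setdefault(child, set())
        if parent:
            parents.setdefault(parent, set())
            parents[child].add(parent)
        if "child_fsn" in df.columns:
            name = str(getattr(row, "child_fsn", "")).strip()
            if name:
                fsn[child] = name
    concepts = [
        Concept(id=cid, fsn=fsn.get(cid, ""), parent_ids=frozenset(ps))
        for cid, ps in parents.items()
    ]
    return Ontology(concepts)


def _load_rf2(concept_source: str | Path, relationship_source: str | Path) -> Ontology:
    cdf = _read_tsv(concept_source)
    _require_columns(cdf, ["id", "active"], concept_source)
    if cdf.empty:
        raise OntologyError(f"{concept_source}: no concept rows")
    rdf = _read_tsv(relationship_source)
    _require_columns(
        rdf, ["sourceId", "destinationId", "typeId", "active"], relationship_source
    )
    active = {str(r.id).strip(): str(r.active).strip() == "1" for r in cdf.itertuples()}
    fsn: dict[str, str] = {}
    if "fsn" in cdf.columns:
        for r in cdf.itertuples():
            fsn[str(r.id).strip()] = str(r.fsn).strip()
    parents: dict[str, set[str]] = {cid: set() for cid in active}
    isa = rdf[(rdf["typeId"] == ISA_TYPE_ID) & (rdf["active"] == "1")]
    for row in isa.itertuples(index=False):
        child = str(row.sourceId).strip()
        parent = str(row.destinationId).strip()
        if child not in active:
            raise DanglingParentError(
                f"{relationship_source}: is-a row references unknown sourceId {child!r}"
            )
        parents[child].add(parent)
    concepts = [
        Concept(id=cid, fsn=fsn.get(cid, ""), active=act, parent_ids=frozenset(parents[cid]))
        for cid, act in active.items()
    ]
    return Ontology(concepts)


def load_ontology(
    concept_source: str | Path,
    relationship_source: str | Path | None = None,
    dialect: str = "edge_list",
) -> Ontology:
    """Load an :class:`Ontology` from tabular files.

    Parameters
    ----------
    concept_source
        For ``edge_list``, the single edge TSV; for ``rf2_snapshot``, the RF2
        concept file.
    relationship_source
        RF2 relationship file (``rf2_snapshot`` only).
    dialect
        ``"edge_list"`` or ``"rf2_snapshot"``.
    """
    if dialect == "edge_list":
        return _load_edge_list(concept_source)
    if dialect == "rf2_snapshot":
        if relationship_source is None:
            raise OntologyError("rf2_snapshot dialect requires a relationship file")
        return _load_rf2(concept_source, relationship_source)
    raise OntologyError(f"unknown ontology dialect {dialect!r}")
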