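"""Clinical-system groupers: subsumption value sets with Boolean exclusion.

A grouper names a clinical system (Cardiovascular, Oncology, ...) and is
defined *intensionally* by a small set of include roots and exclude roots in
the concept hierarchy. Its member set is

    members = desc-or-self(include_roots)  \\  desc-or-self(exclude_roots)

so a handful of high-level concepts covers thousands of descendants, and
carve-outs (e.g. skin cancers pulled out of Oncology into Dermatology) are a
single exclude root. Exclusion always dominates inclusion: a concept
reachable from both an include root and an exclude root — possible under a
polyhierarchy — is not a member.

Classification walks the groupers in ascending rank order and assigns a
concept to the first grouper whose member test passes; a concept matched by
no grouper (or an entry with no usable mapping) lands in the "Other"
section, which always sorts last. When a concept satisfies several groupers
the lowest rank wins, deterministically, and the full match list is kept as
a diagnostic trace.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml

from .errors import GrouperError, UnknownConceptError
from .mapping import MappingPolicy, MappingTable, map_diagnosis
from .ontology import Ontology

OTHER_NAME = "Other"
OTHER_RANK = 22

#: The 21 system/condition groupers in presentation order, plus "Other" last.
SYSTEM_GROUPER_NAMES: tuple[tuple[int, str], ...] = (
    (1, "Care Coordination"),
    (2, "Oncology"),
    (3, "Cardiovascular and Peripheral Vascular"),
    (4, "Respiratory and Allergy"),
    (5, "Endocrine"),
    (6, "Behavioral Health"),
    (7, "Transplant"),
    (8, "Infectious Disease, Immune, or Lymphatic"),
    (9, "Blood"),
    (10, "Neurology or Sleep"),
    (11, "Ears, Nose, Throat (ENT)"),
    (12, "Fluids, Electrolytes, Nutrition, and Gastrointestinal"),
    (13, "Obstetrics and Gynecology"),
    (14, "Genitourinary and Nephrology"),
    (15, "Dermatology"),
    (16, "Rheumatology"),
    (17, "Orthopedic and Musculoskeletal"),
    (18, "Ophthalmology or Eye"),
    (19, "Genetics"),
    (20, "Pediatrics"),
    (21, "Surgery, Trauma, Wound, and Pain"),
)

WithinGroupOrder = Literal["date_then_alpha", "alpha"]


@dataclass(frozen=True)
class GrouperDefinition:
    """A named, ranked include/exclude root-set definition."""

    name: str
    rank: int
    include_roots: frozenset[str]
    exclude_roots: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise GrouperError("grouper name must be nonempty")
        if self.name == OTHER_NAME:
            raise GrouperError('"Other" is the implicit fallback, not a defined grouper')
        if not 1 <= self.rank < OTHER_RANK:
            raise GrouperError(
                f"grouper {self.name!r}: rank must be in [1, {OTHER_RANK - 1}]"
            )
        if not self.include_roots:
            raise GrouperError(f"grouper {self.name!r}: include_roots must be nonempty")


@dataclass(frozen=True)
class CompiledGrouper:
    """A definition materialized against one ontology.

    ``members`` is the extensional member set; membership of concept c holds
    iff some include root subsumes c and no exclude root does.
    """

    definition: GrouperDefinition
    members: frozenset[str]
    ontology: Ontology = field(compare=False, repr=False)

    @property
    def name(self) -> str:
        return self.definition.name

    @property
    def rank(self) -> int:
        return self.definition.rank

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.members


@dataclass(frozen=True)
class ProblemEntry:
    """One problem-list item as extracted from the EHR."""

    entry_id: str
    icd_code: str
    display_text: str = ""
    noted_date: dt.date | None = None
    overview_text: str = ""


@dataclass(frozen=True)
class GrouperAssignment:
    """Where one entry (or bare concept) landed and why."""

    entry_id: str
    grouper_name: str
    rank: int
    matched_concept: str | None
    multi_match: bool
    match_trace: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        assert (self.grouper_name == OTHER_NAME) == (self.rank == OTHER_RANK)


@dataclass(frozen=True)
class Section:
    name: str
    rank: int
    items: tuple[tuple[ProblemEntry, GrouperAssignment], ...]

    @property
    def entries(self) -> tuple[ProblemEntry, ...]:
        return tuple(e for e, _ in self.items)


@dataclass(frozen=True)
class GroupedProblemList:
    """Priority-ordered sectioned output; every input entry appears once."""

    sections: tuple[Section, ...]
    unmapped_count: int

    @property
    def assignments(self) -> tuple[GrouperAssignment, ...]:
        return tuple(a for s in self.sections for _, a in s.items)

    def __len__(self) -> int:
        return sum(len(s.items) for s in self.sections)


# ---------------------------------------------------------------------------
# definitions I/O


def load_grouper_definitions(source: str | Path) -> list[GrouperDefinition]:
    """Read definitions from YAML or JSON (``{groupers: [...]}`` schema)."""
    with open(source, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groupers" not in doc:
        raise GrouperError(f"{source}: expected a mapping with a 'groupers' key")
    defs = []
    for item in doc["groupers"]:
        defs.append(
            GrouperDefinition(
                name=str(item["name"]),
                rank=int(item["rank"]),
                include_roots=frozenset(str(r) for r in item.get("include_roots", [])),
                exclude_roots=frozenset(str(r) for r in item.get("exclude_roots", [])),
            )
        )
    ranks = [d.rank for d in defs]
    if len(set(ranks)) != len(ranks):
        raise GrouperError(f"{source}: duplicate ranks in grouper definitions")
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise GrouperError(f"{source}: duplicate grouper names")
    return sorted(defs, key=lambda d: d.rank)


def save_grouper_definitions(defs: Sequence[GrouperDefinition], dest: str | Path) -> None:
    doc = {
        "groupers": [
            {
                "name": d.name,
                "rank": d.rank,
                "include_roots": sorted(d.include_roots),
                "exclude_roots": sorted(d.exclude_roots),
            }
            for d in sorted(defs, key=lambda d: d.rank)
        ]
    }
    with open(dest, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# compilation and classification


def compile_grouper(definition: GrouperDefinition, ontology: Ontology) -> CompiledGrouper:
    """Materialize a definition's member set against an ontology.

    Raises :class:`GrouperError` naming the grouper and root if any root is
    unknown or inactive.
    """
    include: set[str] = set()
    exclude: set[str] = set()
    for roots, acc in ((definition.include_roots, include), (definition.exclude_roots, exclude)):
        for r in sorted(roots):
            try:
                acc |= ontology.descendants_or_self(r)
            except UnknownConceptError as exc:
                raise GrouperError(
                    f"grouper {definition.name!r}: bad root {r!r} ({exc})"
                ) from None
    return CompiledGrouper(definition, frozenset(include - exclude), ontology)


def compile_groupers(
    definitions: Iterable[GrouperDefinition], ontology: Ontology
) -> list[CompiledGrouper]:
    """Compile a definition set, returned in ascending rank order."""
    return sorted(
        (compile_grouper(d, ontology) for d in definitions), key=lambda g: g.rank
    )


def _other_assignment(entry_id: str) -> GrouperAssignment:
    return GrouperAssignment(entry_id, OTHER_NAME, OTHER_RANK, None, False, ())


def classify_concept(
    concept_id: str,
    groupers: Sequence[CompiledGrouper],
    entry_id: str | None = None,
) -> GrouperAssignment:
    """Assign one concept to the lowest-rank matching grouper, else Other.

    ``multi_match`` is set when more than one grouper matches; every match is
    recorded in ``match_trace`` as (grouper name, include root that subsumes
    the concept).
    """
    eid = entry_id if entry_id is not None else concept_id
    trace: list[tuple[str, str]] = []
    for g in sorted(groupers, key=lambda g: g.rank):
        if concept_id in g:
            root = next(
                r
                for r in sorted(g.definition.include_roots)
                if g.ontology.subsumes(r, concept_id)
            )
            trace.append((g.name, root))
    if not trace:
        return _other_assignment(eid)
    name, _ = trace[0]
    rank = next(g.rank for g in groupers if g.name == name)
    return GrouperAssignment(
        eid, name, rank, concept_id, len(trace) > 1, tuple(trace)
    )


def _entry_sort_key(order: WithinGroupOrder):
    if order == "alpha":
        return lambda item: (item[0].display_text.lower(), item[0].entry_id)
    if order == "date_then_alpha":
        # recent first; undated entries last
        def key(item):
            e = item[0]
            ord_ = -e.noted_date.toordinal() if e.noted_date is not None else float("inf")
            return (ord_, e.display_text.lower(), e.entry_id)

        return key
    raise GrouperError(f"unknown within_group_order {order!r}")


def organize_problem_list(
    entries: Sequence[ProblemEntry],
    table: MappingTable,
    groupers: Sequence[CompiledGrouper],
    ontology: Ontology,
    policy: MappingPolicy = "primary_only",
    within_group_order: WithinGroupOrder = "date_then_alpha",
) -> GroupedProblemList:
    """Map, classify and section a problem list.

    Each entry is mapped to concepts via ``map_diagnosis`` and classified;
    under ``policy="all"`` the entry takes the best (lowest) rank over all
    its mapped concepts. Entries that are unmapped, or mapped only onto
    concepts absent/inactive in the ontology, go to "Other" and are counted
    in ``unmapped_count``.
    """
    for g in groupers:
        if g.ontology is not ontology:
            raise GrouperError(
                f"grouper {g.name!r} was compiled against a different ontology"
            )
    groupers = sorted(groupers, key=lambda g: g.rank)
    ids = [e.entry_id for e in entries]
    if len(set(ids)) != len(ids):
        raise GrouperError("duplicate entry_id in problem list")

    unmapped = 0
    assigned: dict[str, list[tuple[ProblemEntry, GrouperAssignment]]] = {}
    for entry in entries:
        concepts = [
            c
            for c in map_diagnosis(entry.icd_code, table, policy)
            if c in ontology and ontology.is_active(c)
        ]
        if not concepts:
            unmapped += 1
            a = _other_assignment(entry.entry_id)
        else:
            a = min(
                (classify_concept(c, groupers, entry.entry_id) for c in concepts),
                key=lambda a: a.rank,
            )
        assigned.setdefault(a.grouper_name, []).append((entry, a))

    key = _entry_sort_key(within_group_order)
    rank_of = {g.name: g.rank for g in groupers}
    rank_of[OTHER_NAME] = OTHER_RANK
    sections = tuple(
        Section(name, rank_of[name], tuple(sorted(items, key=key)))
        for name, items in sorted(assigned.items(), key=lambda kv: rank_of[kv[0]])
    )
    return GroupedProblemList(sections, unmapped)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise member-set intersections, sizes, and empty groupers."""

    sizes: dict[str, int]
    overlaps: dict[tuple[str, str], int]
    empty: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "sizes": dict(self.sizes),
            "overlaps": [
                {"groupers": list(pair), "count": n} for pair, n in self.overlaps.items()
            ],
            "empty": list(self.empty),
        }


def validate_groupers(
    definitions: Sequence[GrouperDefinition], ontology: Ontology
) -> OverlapReport:
    """Compile a definition set and report overlaps and degenerate members."""
    compiled = compile_groupers(definitions, ontology)
    sizes = {g.name: len(g.members) for g in compiled}
    overlaps: dict[tuple[str, str], int] = {}
    for i, a in enumerate(compiled):
        for b in compiled[i + 1 :]:
            overlaps[(a.name, b.name)] = len(a.members & b.members)
    empty = tuple(g.name for g in compiled if not g.members)
    return OverlapReport(sizes, overlaps, empty)


# ---------------------------------------------------------------------------
# problem-list I/O


def read_problem_list(source: str | Path) -> list[ProblemEntry]:
    """Read a problem-list CSV (entry_id, icd_code, display_text, noted_date,
    overview_text); dates are ISO 8601, blank for undated."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    for col in ("entry_id", "icd_code"):
        if col not in df.columns:
            raise GrouperError(f"{source}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        raw_date = str(getattr(row, "noted_date", "")).strip()
        noted = dt.date.fromisoformat(raw_date) if raw_date else None
        out.append(
            ProblemEntry(
                entry_id=str(row.entry_id),
                icd_code=str(row.icd_code),
                display_text=str(getattr(row, "display_text", "")),
                noted_date=noted,
                overview_text=str(getattr(row, "overview_text", "")),
            )
        )
    return out


def grouped_to_dict(grouped: GroupedProblemList) -> dict:
    return {
        "unmapped_count": grouped.unmapped_count,
        "sections": [
            {
                "name": s.name,
                "rank": s.rank,
                "entries": [
                    {
                        "entry_id": e.entry_id,
                        "icd_code": e.icd_code,
                        "display_text": e.display_text,
                        "noted_date": e.noted_date.isoformat() if e.noted_date else None,
                        "matched_concept": a.matched_concept,
                        "multi_match": a.multi_match,
                    }
                    for e, a in s.items
                ],
            }
            for s in grouped.sections
        ],
    }


def write_grouped_json(grouped: GroupedProblemList, dest: str | Path) -> None:
    with open(dest, "w", encoding="utf-8") as fh:
        json.dump(grouped_to_dict(grouped), fh, indent=2)
        fh.write("\n")


def write_assignments_csv(grouped: GroupedProblemList, dest: str | Path) -> None:
    rows = [
        {
            "entry_id": a.entry_id,
            "grouper_name": a.grouper_name,
            "rank": a.rank,
            "matched_concept": a.matched_concept or "",
            "multi_match": int(a.multi_match),
        }
        for a in grouped.assignments
    ]
    pd.DataFrame(
        rows, columns=["entry_id", "grouper_name", "rank", "matched_concept", "multi_match"]
    ).to_csv(dest, index=False)
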