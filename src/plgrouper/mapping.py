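"""ICD-10-CM → SNOMED-style diagnosis mapping tables.

Problem-list entries are coded in ICD-10-CM, while groupers operate on
ontology concepts; a vendor-style mapping table bridges the two. Mappings are
many-to-many in practice: one ICD code may map to several concepts (one of
which is the *primary* map), and several ICD codes may share a concept. An
unmapped code is a legitimate outcome, not an error — such entries fall to
the "Other" section downstream.

The table format is a TSV with columns ``icd_code``, ``concept_id`` and an
optional ``is_primary`` (0/1) flag. When no row for a code is explicitly
flagged primary, the first row wins.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import MappingError

logger = logging.getLogger(__name__)

# letter, then digits, then an optional dot-suffix of alphanumerics
# (ICD-10-CM 7th characters may be letters, e.g. S06.0X1A)
_ICD_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]{0,5}(\.[0-9A-Z]{1,4})?$")

MappingPolicy = Literal["primary_only", "all"]


def normalize_icd(code: str) -> str:
    """Canonicalize an ICD-10-CM code to upper-case dotted form.

    Undotted input longer than three characters gets a dot inserted after
    position 3 (``"Z91038" -> "Z91.038"``).
    """
    code = code.strip().upper()
    if "." not in code and len(code) > 3:
        code = code[:3] + "." + code[3:]
    return code


def is_valid_icd(code: str) -> bool:
    return bool(_ICD_RE.match(code))


@dataclass(frozen=True)
class MappingEntry:
    icd_code: str
    concept_id: str
    is_primary: bool = False


class MappingTable:
    """An indexed collection of :class:`MappingEntry` rows.

    Invariants: no duplicate ``(icd_code, concept_id)`` pair; at most one
    primary entry per code.
    """

    def __init__(self, entries: Iterable[MappingEntry]):
        self._by_code: dict[str, list[MappingEntry]] = {}
        seen: set[tuple[str, str]] = set()
        for e in entries:
            key = (e.icd_code, e.concept_id)
            if key in seen:
                continue
            seen.add(key)
            self._by_code.setdefault(e.icd_code, []).append(e)
        for code, rows in self._by_code.items():
            n_primary = sum(r.is_primary for r in rows)
            if n_primary > 1:
                raise MappingError(f"code {code!r} has {n_primary} primary mappings")
            if n_primary == 0:
                rows[0] = MappingEntry(rows[0].icd_code, rows[0].concept_id, True)

    @property
    def entries(self) -> list[MappingEntry]:
        return [e for rows in self._by_code.values() for e in rows]

    def __len__(self) -> int:
        return len(self.entries)

    def codes(self) -> set[str]:
        return set(self._by_code)

    def lookup(self, icd_code: str) -> list[MappingEntry]:
        """All entries for a code, primary first; empty list if unmapped."""
        rows = self._by_code.get(normalize_icd(icd_code), [])
        return sorted(rows, key=lambda e: not e.is_primary)


def map_diagnosis(
    icd_code: str, table: MappingTable, policy: MappingPolicy = "primary_only"
) -> list[str]:
    """Concept ids mapped to an ICD code under the given policy.

    ``primary_only`` returns the primary concept (or nothing); ``all``
    returns every mapped concept, primary first. Unmapped codes yield an
    empty list.
    """
    rows = table.lookup(icd_code)
    if policy == "primary_only":
        return [r.concept_id for r in rows if r.is_primary][:1]
    if policy == "all":
        return [r.concept_id for r in rows]
    raise MappingError(f"unknown mapping policy {policy!r}")


def load_mapping(source: str | Path) -> MappingTable:
    """Load a mapping TSV; malformed ICD rows are skipped with a warning."""
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return MappingTable([])
    for col in ("icd_code", "concept_id"):
        if col not in df.columns:
            raise MappingError(f"{source}: missing required column {col!r}")
    has_flag = "is_primary" in df.columns
    # explicit primary flags take precedence; rows without a flag fall back
    # to first-row-wins inside MappingTable
    entries: list[MappingEntry] = []
    for row in df.itertuples(index=False):
        code = normalize_icd(str(row.icd_code))
        if not is_valid_icd(code):
            logger.warning("%s: rejecting malformed ICD code %r", source, row.icd_code)
            continue
        concept = str(row.concept_id).strip()
        if not concept:
            logger.warning("%s: rejecting row for %r with empty concept_id", source, code)
            continue
        primary = has_flag and str(row.is_primary).strip() == "1"
        entries.append(MappingEntry(code, concept, primary))
    return MappingTable(entries)


def save_mapping(table: MappingTable, dest: str | Path) -> None:
    """Write a table back to TSV; ``load_mapping`` round-trips it."""
    df = pd.DataFrame(
        [
            {"icd_code": e.icd_code, "concept_id": e.concept_id,
             "is_primary": int(e.is_primary)}
            for e in table.entries
        ],
        columns=["icd_code", "concept_id", "is_primary"],
    )
    df.to_csv(dest, sep="\t", index=False)
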