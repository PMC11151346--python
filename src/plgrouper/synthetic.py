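"""Synthetic fixtures: toy ontologies, mappings, and problem lists with gold.

Everything downstream (grouping, evaluation) is exercised against generated
data with known ground truth, because real SNOMED CT releases, vendor
mapping content and patient problem lists cannot be redistributed. The
generator emulates the structural features that matter to the method:

* a rooted is-a DAG whose first level holds one subtree per clinical system,
  plus a pool of over-general "clinical finding"-style concepts attached
  only to the root (these are attributable to no system — the "Other" mass);
* optional polyhierarchy (a concept gains a second parent within its
  system);
* *exclusion grafts*: a subtree physically placed inside one system's
  subtree but truly belonging to another (the way dermatologic cancers sit
  under the neoplasm hierarchy), which is exactly the case the groupers'
  Boolean exclusion exists for;
* a diagnosis mapping with over-generalization noise (a mapped concept
  replaced by an unattributable ancestor), unmapped codes, and fabricated
  ICD-style codes;
* per-patient diagnosis counts drawn from a discretized log-normal with
  median ≈ 12, clamped to [4, 59] — a right-skewed load whose mean (~17)
  exceeds its median, matching real problem-list burden.

Gold labels are generative: each entry's gold grouper is the system its
*true* concept belongs to ("Other" for pool concepts and unmapped entries).
An over-generalized mapping therefore scores as a false negative for a
system-attributable entry, which makes the generator's noise rate ε an
oracle for the pipeline's expected FN+FP rate.

Identical config + seed produces byte-identical output files.
"""

from __future__ import annotations

import datetime as dt
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

from .errors import ConfigError
from .groupers import (
    SYSTEM_GROUPER_NAMES,
    CompiledGrouper,
    GrouperDefinition,
    OTHER_NAME,
    ProblemEntry,
    compile_groupers,
    save_grouper_definitions,
)
from .mapping import MappingEntry, MappingTable, save_mapping
from .ontology import Concept, Ontology


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults reproduce the study conditions
    (50 patients, median 12 problems in [4, 59], ~4% over-general/"Other"
    mass, ~2% over-generalized mappings, ~1% unmapped)."""

    n_concepts: int = 400
    n_systems: int = 21
    polyhierarchy_prob: float = 0.05
    exclusion_graft_prob: float = 0.3
    n_patients: int = 50
    median_problems: float = 12.0
    sigma_problems: float = 0.86
    min_problems: int = 4
    max_problems: int = 59
    other_concept_prob: float = 0.033
    mapping_noise: float = 0.022
    unmapped_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "polyhierarchy_prob",
            "exclusion_graft_prob",
            "other_concept_prob",
            "mapping_noise",
            "unmapped_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not 1 <= self.n_systems <= len(SYSTEM_GROUPER_NAMES):
            raise ConfigError(
                f"n_systems must be in [1, {len(SYSTEM_GROUPER_NAMES)}]"
            )
        if self.n_systems > self.n_concepts - 2:
            raise ConfigError("infeasible: need n_systems <= n_concepts - 2")
        if self.n_patients < 0 or self.min_problems > self.max_problems:
            raise ConfigError("invalid patient/problem-count configuration")


@dataclass(frozen=True)
class SyntheticOntology:
    """A generated hierarchy plus its generative ground truth."""

    ontology: Ontology
    labels: Mapping[str, str | None]  # concept id -> system name, None = no system
    root_id: str
    system_roots: Mapping[str, str]  # system name -> subtree root id
    graft_roots: tuple[tuple[str, str, str], ...]  # (graft id, true system, host system)
    pool_ids: frozenset[str]


@dataclass(frozen=True)
class GoldLabel:
    entry_id: str
    gold_grouper: str


@dataclass(frozen=True)
class SyntheticStudy:
    """Problem lists with mapping and per-entry gold labels."""

    entries: tuple[ProblemEntry, ...]
    mapping: MappingTable
    gold: tuple[GoldLabel, ...]
    true_concepts: Mapping[str, str]  # entry_id -> originating concept
    patients: tuple[dict, ...] = field(default_factory=tuple)


def _system_names(n: int) -> list[str]:
    return [name for _, name in SYSTEM_GROUPER_NAMES[:n]]


def generate_ontology(config: SynthConfig) -> SyntheticOntology:
    """Grow a labeled DAG: root, system subtrees, root pool, grafts,
    optional second parents (always within the same system)."""
    rng = random.Random(config.seed)
    names = _system_names(config.n_systems)

    next_id = [1000001]

    def new_id() -> str:
        i = next_id[0]
        next_id[0] += 1
        return str(i)

    concepts: list[Concept] = []
    labels: dict[str, str | None] = {}
    # the system whose subtree physically contains a node (host system for
    # graft descendants); used to keep grafts from nesting inside foreign
    # graft subtrees, which would let two systems' excludes annihilate them
    phys: dict[str, str | None] = {}
    by_label: dict[str | None, list[str]] = {s: [] for s in names}
    by_label[None] = []

    root = new_id()
    concepts.append(Concept(root, "Clinical finding (synthetic root)"))
    labels[root] = None
    phys[root] = None

    system_roots: dict[str, str] = {}
    for s in names:
        cid = new_id()
        concepts.append(Concept(cid, f"Disorder of {s} (synthetic)", parent_ids=frozenset({root})))
        labels[cid] = s
        phys[cid] = s
        by_label[s].append(cid)
        system_roots[s] = cid

    budget = config.n_concepts - 1 - config.n_systems
    n_pool = min(budget, max(1, round(0.05 * config.n_concepts)))
    for i in range(n_pool):
        cid = new_id()
        concepts.append(
            Concept(cid, f"Nonspecific finding {i} (synthetic)", parent_ids=frozenset({root}))
        )
        labels[cid] = None
        phys[cid] = None
        by_label[None].append(cid)
    budget -= n_pool

    graft_roots: list[tuple[str, str, str]] = []

    def make_grafts() -> None:
        # exclusion grafts: per system, Bernoulli(p) that it hosts one
        # foreign subtree; the attachment point is genuine host territory
        nonlocal budget
        if config.n_systems < 2:
            return
        for host in names:
            if budget <= 0:
                break
            if rng.random() >= config.exclusion_graft_prob:
                continue
            donor = rng.choice([s for s in names if s != host])
            anchors = [c for c in by_label[host] if phys[c] == host]
            parent = rng.choice(anchors)
            cid = new_id()
            concepts.append(
                Concept(
                    cid,
                    f"{donor} condition grafted under {host} (synthetic)",
                    parent_ids=frozenset({parent}),
                )
            )
            labels[cid] = donor
            phys[cid] = host
            by_label[donor].append(cid)
            graft_roots.append((cid, donor, host))
            budget -= 1

    # grow concepts with grafts inserted mid-way so graft placement varies;
    # parent drawn among same-label nodes, so graft subtrees keep growing
    # inside their host system
    n_first_half = budget // 2
    i = 0
    while budget > 0:
        if i == n_first_half:
            make_grafts()
            if budget <= 0:
                break
        label = rng.choice(names)
        primary = rng.choice(by_label[label])
        parents = {primary}
        if rng.random() < config.polyhierarchy_prob and len(by_label[label]) > 1:
            extra = rng.choice(by_label[label])
            parents.add(extra)
        cid = new_id()
        concepts.append(
            Concept(cid, f"{label} disorder {i} (synthetic)", parent_ids=frozenset(parents))
        )
        labels[cid] = label
        phys[cid] = phys[primary]
        by_label[label].append(cid)
        budget -= 1
        i += 1

    return SyntheticOntology(
        ontology=Ontology(concepts),
        labels=labels,
        root_id=root,
        system_roots=system_roots,
        graft_roots=tuple(graft_roots),
        pool_ids=frozenset(by_label[None]),
    )


def generate_groupers(synth: SyntheticOntology) -> list[GrouperDefinition]:
    """One definition per system: the subtree root plus any graft roots the
    system truly owns as includes; graft roots physically inside a system
    but owned elsewhere as its excludes."""
    include: dict[str, set[str]] = {s: {r} for s, r in synth.system_roots.items()}
    exclude: dict[str, set[str]] = {s: set() for s in synth.system_roots}
    for graft_id, donor, host in synth.graft_roots:
        include[donor].add(graft_id)
        exclude[host].add(graft_id)
    rank_of = dict((name, rank) for rank, name in SYSTEM_GROUPER_NAMES)
    return [
        GrouperDefinition(
            name=s,
            rank=rank_of[s],
            include_roots=frozenset(include[s]),
            exclude_roots=frozenset(exclude[s]),
        )
        for s in synth.system_roots
    ]


def _draw_count(rng: random.Random, config: SynthConfig) -> int:
    mu = math.log(config.median_problems)
    x = round(math.exp(rng.gauss(mu, config.sigma_problems)))
    return max(config.min_problems, min(config.max_problems, x))


def _fabricate_icd(index: int) -> str:
    # synthetic letter+digits codes; no real ICD-10-CM semantics implied
    return f"{chr(ord('A') + index % 26)}{index:05d}"


def generate_problem_lists(
    synth: SyntheticOntology,
    groupers: list[GrouperDefinition] | list[CompiledGrouper],
    config: SynthConfig,
) -> SyntheticStudy:
    """Draw patients and entries; fabricate codes, mapping rows and gold.

    Gold is the true concept's system ("Other" for pool concepts and for
    entries whose mapping row is dropped). With probability
    ``mapping_noise`` the mapping row points at an unattributable strict
    ancestor of the true concept instead, which downstream lands in "Other".
    """
    rng = random.Random(config.seed + 1)
    compiled = (
        groupers
        if groupers and isinstance(groupers[0], CompiledGrouper)
        else compile_groupers(groupers, synth.ontology)  # type: ignore[arg-type]
    )
    attributable = set().union(*(g.members for g in compiled)) if compiled else set()

    system_concepts = sorted(c for c, s in synth.labels.items() if s is not None)
    pool_concepts = sorted(synth.pool_ids)
    onto = synth.ontology

    entries: list[ProblemEntry] = []
    mapping_rows: list[MappingEntry] = []
    gold: list[GoldLabel] = []
    true_concepts: dict[str, str] = {}
    patients: list[dict] = []
    base_date = dt.date(2019, 1, 1)

    idx = 0
    for p in range(config.n_patients):
        count = _draw_count(rng, config)
        patients.append(
            {
                "patient_id": f"PT{p:04d}",
                "age": rng.randint(0, 93),
                "sex": rng.choice(["F", "M"]),
                "n_problems": count,
            }
        )
        for j in range(count):
            entry_id = f"PT{p:04d}-{j:03d}"
            if pool_concepts and rng.random() < config.other_concept_prob:
                concept = rng.choice(pool_concepts)
            else:
                concept = rng.choice(system_concepts)
            icd = _fabricate_icd(idx)
            icd_dotted = icd[:3] + "." + icd[3:]
            idx += 1
            noted = base_date + dt.timedelta(days=rng.randint(0, 1095))
            entries.append(
                ProblemEntry(
                    entry_id=entry_id,
                    icd_code=icd_dotted,
                    display_text=onto[concept].fsn or concept,
                    noted_date=noted,
                    overview_text="",
                )
            )
            true_concepts[entry_id] = concept

            u = rng.random()
            if u < config.unmapped_prob:
                gold.append(GoldLabel(entry_id, OTHER_NAME))
                continue
            if u < config.unmapped_prob + config.mapping_noise:
                candidates = sorted(
                    a for a in onto.ancestors(concept) if a not in attributable
                )
                mapped = rng.choice(candidates) if candidates else synth.root_id
            else:
                mapped = concept
            mapping_rows.append(MappingEntry(icd_dotted, mapped, True))
            gold.append(GoldLabel(entry_id, synth.labels[concept] or OTHER_NAME))

    return SyntheticStudy(
        entries=tuple(entries),
        mapping=MappingTable(mapping_rows),
        gold=tuple(gold),
        true_concepts=true_concepts,
        patients=tuple(patients),
    )


# ---------------------------------------------------------------------------
# file bundle


@dataclass(frozen=True)
class SyntheticBundle:
    synth: SyntheticOntology
    definitions: list[GrouperDefinition]
    study: SyntheticStudy
    paths: dict[str, Path]


def write_ontology_edges(ontology: Ontology, dest: str | Path) -> None:
    with open(dest, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("child_id\tparent_id\tchild_fsn\n")
        for cid in sorted(ontology.concepts):
            c = ontology.concepts[cid]
            if not c.parent_ids:
                fh.write(f"{cid}\t\t{c.fsn}\n")
            for p in sorted(c.parent_ids):
                fh.write(f"{cid}\t{p}\t{c.fsn}\n")


def write_problem_list(entries: tuple[ProblemEntry, ...], dest: str | Path) -> None:
    with open(dest, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("entry_id,icd_code,display_text,noted_date,overview_text\n")
        for e in entries:
            date = e.noted_date.isoformat() if e.noted_date else ""
            fh.write(f'{e.entry_id},{e.icd_code},"{e.display_text}",{date},"{e.overview_text}"\n')


def write_gold_labels(gold: tuple[GoldLabel, ...], dest: str | Path) -> None:
    with open(dest, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("entry_id,gold_grouper\n")
        for g in gold:
            fh.write(f'{g.entry_id},"{g.gold_grouper}"\n')


def generate_bundle(config: SynthConfig, outdir: str | Path) -> SyntheticBundle:
    """Generate everything and write the file formats the other modules
    consume: edge TSV, grouper YAML, mapping TSV, problem CSV, gold CSV,
    patient CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = generate_ontology(config)
    defs = generate_groupers(synth)
    study = generate_problem_lists(synth, defs, config)

    paths = {
        "ontology": outdir / "ontology_edges.tsv",
        "groupers": outdir / "groupers.yaml",
        "mapping": outdir / "mapping.tsv",
        "problems": outdir / "problems.csv",
        "gold": outdir / "gold.csv",
        "patients": outdir / "patients.csv",
    }
    write_ontology_edges(synth.ontology, paths["ontology"])
    save_grouper_definitions(defs, paths["groupers"])
    save_mapping(study.mapping, paths["mapping"])
    write_problem_list(study.entries, paths["problems"])
    write_gold_labels(study.gold, paths["gold"])
    with open(paths["patients"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id,age,sex,n_problems\n")
        for p in study.patients:
            fh.write(f"{p['patient_id']},{p['age']},{p['sex']},{p['n_problems']}\n")
    return SyntheticBundle(synth, defs, study, paths)


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    return replace(config, seed=seed)
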