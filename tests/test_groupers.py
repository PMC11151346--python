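import datetime as dt
import itertools
import random

import pytest

import plgrouper as pg
from conftest import make_random_dag


def brute_force_members(onto, definition):
    """Oracle: full closure set-difference, concept by concept."""
    return {
        c
        for c in onto.concepts
        if onto.is_active(c)
        and any(onto.subsumes(i, c) for i in definition.include_roots)
        and not any(onto.subsumes(e, c) for e in definition.exclude_roots)
    }


class TestCompilation:
    def test_skin_cancer_carved_out_of_oncology(self, toy_ontology, toy_groupers):
        onc = next(g for g in toy_groupers if g.name == "Oncology")
        derm = next(g for g in toy_groupers if g.name == "Dermatology")
        scc = "254651007"  # squamous cell carcinoma of skin
        assert scc not in onc
        assert scc in derm

    def test_self_cancellation_empties_member_set(self, diamond_ontology):
        d = pg.GrouperDefinition(
            "X", 1, include_roots=frozenset({"A"}), exclude_roots=frozenset({"A"})
        )
        assert pg.compile_grouper(d, diamond_ontology).members == frozenset()

    def test_exclusion_wins_on_diamond(self, diamond_ontology):
        # D descends from include root B via one parent, exclude root C via another
        d = pg.GrouperDefinition(
            "X", 1, include_roots=frozenset({"B"}), exclude_roots=frozenset({"C"})
        )
        g = pg.compile_grouper(d, diamond_ontology)
        assert "D" not in g
        assert "B" in g

    def test_unknown_root_names_grouper_and_root(self, diamond_ontology):
        d = pg.GrouperDefinition("Cardio", 3, include_roots=frozenset({"ZZZ"}))
        with pytest.raises(pg.GrouperError, match="Cardio.*ZZZ"):
            pg.compile_grouper(d, diamond_ontology)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        onto = make_random_dag(150, seed)
        rng = random.Random(seed + 100)
        ids = sorted(onto.concepts)
        d = pg.GrouperDefinition(
            "R",
            1,
            include_roots=frozenset(rng.sample(ids, 4)),
            exclude_roots=frozenset(rng.sample(ids, 2)),
        )
        assert pg.compile_grouper(d, onto).members == brute_force_members(onto, d)

    @pytest.mark.parametrize("seed", range(3))
    def test_exclusion_monotonicity(self, seed):
        onto = make_random_dag(100, seed)
        rng = random.Random(seed + 200)
        ids = sorted(onto.concepts)
        include = frozenset(rng.sample(ids, 3))
        excludes: frozenset[str] = frozenset()
        prev = pg.compile_grouper(
            pg.GrouperDefinition("R", 1, include), onto
        ).members
        # removing all excludes gives the raw union of include closures
        union = set().union(*(onto.descendants_or_self(i) for i in include))
        assert prev == union
        for extra in rng.sample(ids, 5):
            excludes = excludes | {extra}
            cur = pg.compile_grouper(
                pg.GrouperDefinition("R", 1, include, excludes), onto
            ).members
            assert cur <= prev  # adding an exclude never adds a member
            prev = cur


class TestClassification:
    def test_overgeneral_finding_falls_to_other(self, toy_groupers):
        a = pg.classify_concept("267038008", toy_groupers)  # edema
        assert a.grouper_name == pg.OTHER_NAME
        assert a.rank == pg.OTHER_RANK
        assert a.matched_concept is None

    def test_single_membership(self, toy_groupers):
        a = pg.classify_concept("49436004", toy_groupers)  # atrial fibrillation
        assert a.grouper_name == "Cardiovascular and Peripheral Vascular"
        assert not a.multi_match

    def test_lowest_rank_wins_with_trace(self, toy_groupers):
        # malignant tumor of lung is both Oncology (2) and Respiratory (4)
        a = pg.classify_concept("363358000", toy_groupers)
        assert a.grouper_name == "Oncology"
        assert a.multi_match
        assert [name for name, _ in a.match_trace] == [
            "Oncology",
            "Respiratory and Allergy",
        ]

    def test_priority_determinism_under_permutation(self, toy_groupers):
        concepts = ["363358000", "49436004", "267038008", "254651007", "385093006"]
        baseline = {c: pg.classify_concept(c, toy_groupers) for c in concepts}
        for perm in itertools.permutations(toy_groupers):
            for c in concepts:
                assert pg.classify_concept(c, list(perm)) == baseline[c]


class TestOrganize:
    def test_paper_style_attribution(self, toy_entries, toy_mapping, toy_groupers, toy_ontology):
        grouped = pg.organize_problem_list(
            toy_entries, toy_mapping, toy_groupers, toy_ontology
        )
        by_entry = {a.entry_id: a.grouper_name for a in grouped.assignments}
        assert by_entry["e01"] == "Respiratory and Allergy"  # lung nodule
        assert by_entry["e02"] == "Oncology"  # lung cancer
        assert by_entry["e03"] == "Dermatology"  # squamous cell carcinoma
        assert by_entry["e04"] == pg.OTHER_NAME  # edema

    def test_empty_input_has_no_sections(self, toy_mapping, toy_groupers, toy_ontology):
        grouped = pg.organize_problem_list([], toy_mapping, toy_groupers, toy_ontology)
        assert grouped.sections == ()
        assert grouped.unmapped_count == 0

    def test_partition_and_unmapped_count(self, toy_entries, toy_mapping, toy_groupers, toy_ontology):
        grouped = pg.organize_problem_list(
            toy_entries, toy_mapping, toy_groupers, toy_ontology
        )
        all_ids = [e.entry_id for s in grouped.sections for e in s.entries]
        assert sorted(all_ids) == sorted(e.entry_id for e in toy_entries)
        assert len(all_ids) == len(set(all_ids)) == 10
        assert grouped.unmapped_count == 2
        other = grouped.sections[-1]
        assert other.name == pg.OTHER_NAME
        assert len(other.items) >= 2

    def test_sections_in_ascending_rank_order(self, toy_entries, toy_mapping, toy_groupers, toy_ontology):
        grouped = pg.organize_problem_list(
            toy_entries, toy_mapping, toy_groupers, toy_ontology
        )
        ranks = [s.rank for s in grouped.sections]
        assert ranks == sorted(ranks)
        assert grouped.sections[-1].rank == pg.OTHER_RANK

    def test_within_section_date_then_alpha(self, toy_mapping, toy_groupers, toy_ontology):
        entries = [
            pg.ProblemEntry("a", "R91.1", "Zeta nodule", dt.date(2020, 1, 1)),
            pg.ProblemEntry("b", "J45.909", "Asthma", dt.date(2021, 5, 5)),
            pg.ProblemEntry("c", "R91.1", "Alpha nodule", dt.date(2020, 1, 1)),
            pg.ProblemEntry("d", "J45.909", "Undated asthma", None),
        ]
        grouped = pg.organize_problem_list(
            entries, toy_mapping, toy_groupers, toy_ontology,
            within_group_order="date_then_alpha",
        )
        (resp,) = grouped.sections
        assert [e.entry_id for e in resp.entries] == ["b", "c", "a", "d"]
        grouped_alpha = pg.organize_problem_list(
            entries, toy_mapping, toy_groupers, toy_ontology,
            within_group_order="alpha",
        )
        assert [e.entry_id for e in grouped_alpha.sections[0].entries] == ["c", "b", "d", "a"]

    def test_ontology_mismatch_rejected(self, toy_entries, toy_mapping, toy_groupers, toy_dir):
        other = pg.load_ontology(toy_dir / "ontology_edges.tsv")
        with pytest.raises(pg.GrouperError, match="different ontology"):
            pg.organize_problem_list(
                toy_entries, toy_mapping, toy_groupers, other
            )

    def test_policy_all_takes_best_rank(self, toy_ontology, toy_groupers):
        # code maps to edema (Other) and to lung cancer (Oncology): "all"
        # recovers the Oncology attribution, "primary_only" stays with edema
        table = pg.MappingTable(
            [
                pg.MappingEntry("R60.9", "267038008", True),
                pg.MappingEntry("R60.9", "363358000", False),
            ]
        )
        entries = [pg.ProblemEntry("x", "R60.9", "odd code")]
        primary = pg.organize_problem_list(
            entries, table, toy_groupers, toy_ontology, policy="primary_only"
        )
        both = pg.organize_problem_list(
            entries, table, toy_groupers, toy_ontology, policy="all"
        )
        assert primary.assignments[0].grouper_name == pg.OTHER_NAME
        assert both.assignments[0].grouper_name == "Oncology"


class TestValidate:
    def test_disjoint_subtrees_have_zero_overlap(self, diamond_ontology):
        defs = [
            pg.GrouperDefinition("Left", 1, frozenset({"B"}), frozenset({"D"})),
            pg.GrouperDefinition("Right", 2, frozenset({"C"}), frozenset({"D"})),
        ]
        report = pg.validate_groupers(defs, diamond_ontology)
        assert report.overlaps[("Left", "Right")] == 0
        assert report.empty == ()

    def test_shared_subtree_reported(self, diamond_ontology):
        defs = [
            pg.GrouperDefinition("Left", 1, frozenset({"B"})),
            pg.GrouperDefinition("Right", 2, frozenset({"C"})),
        ]
        report = pg.validate_groupers(defs, diamond_ontology)
        assert report.overlaps[("Left", "Right")] == 1  # D reachable from both

    def test_self_cancelled_grouper_flagged_empty(self, diamond_ontology):
        defs = [pg.GrouperDefinition("Gone", 1, frozenset({"B"}), frozenset({"B"}))]
        report = pg.validate_groupers(defs, diamond_ontology)
        assert report.empty == ("Gone",)
        assert report.sizes["Gone"] == 0


class TestDefinitionValidation:
    def test_empty_include_roots_rejected(self):
        with pytest.raises(pg.GrouperError):
            pg.GrouperDefinition("X", 1, frozenset())

    def test_rank_bounds(self):
        with pytest.raises(pg.GrouperError):
            pg.GrouperDefinition("X", 22, frozenset({"a"}))

    def test_duplicate_ranks_rejected(self, tmp_path):
        p = tmp_path / "g.yaml"
        p.write_text(
            "groupers:\n"
            "  - {name: A, rank: 1, include_roots: [x]}\n"
            "  - {name: B, rank: 1, include_roots: [y]}\n"
        )
        with pytest.raises(pg.GrouperError, match="duplicate ranks"):
            pg.load_grouper_definitions(p)

    def test_yaml_json_equivalent(self, tmp_path, toy_dir):
        import json

        import yaml

        doc = yaml.safe_load((toy_dir / "groupers.yaml").read_text())
        j = tmp_path / "g.json"
        j.write_text(json.dumps(doc))
        assert pg.load_grouper_definitions(j) == pg.load_grouper_definitions(
            toy_dir / "groupers.yaml"
        )
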