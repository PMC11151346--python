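"""Reorganize the bundled toy problem list into clinical-system sections.

Loads the small bundled ontology/mapping/grouper fixture, runs the grouping
pipeline on a 10-entry problem list, and prints the sectioned result. Note
the carve-out in action: squamous cell carcinoma of skin descends from the
malignant-neoplasm include root of Oncology but is excluded there and lands
in Dermatology, while lung cancer (a member of both the Oncology and the
Respiratory member sets) takes the lower rank, Oncology.
"""

import plgrouper as pg

toy = pg.toy_fixture_dir()
onto = pg.load_ontology(toy / "ontology_edges.tsv", dialect="edge_list")
groupers = pg.compile_groupers(pg.load_grouper_definitions(toy / "groupers.yaml"), onto)
table = pg.load_mapping(toy / "mapping.tsv")
entries = pg.read_problem_list(toy / "problems.csv")

grouped = pg.organize_problem_list(entries, table, groupers, onto)

for section in grouped.sections:
    print(f"[{section.rank:>2}] {section.name}")
    for entry, assignment in section.items:
        flag = " (multi-system)" if assignment.multi_match else ""
        print(f"      {entry.icd_code:<8} {entry.display_text}{flag}")
print(f"\nentries: {len(grouped)}, unmapped: {grouped.unmapped_count}")
# Sections appear in grouper rank order with "Other" last; unmapped codes
# (no row in the mapping table) are counted and default to "Other".
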