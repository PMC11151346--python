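"""plgrouper: organize EHR problem lists by clinical system.

Problem lists accumulate diagnoses faster than anyone curates them. This
package reorganizes a coded problem list into clinical-system sections using
subsumption groupers over an is-a concept polyhierarchy (SNOMED CT-shaped),
with Boolean exclusion logic and a ranked "Other" fallback — and provides the
evaluation machinery (reviewer categories, agreement, Cohen κ, confusion
metrics) to measure how well the grouping matches clinician judgment.

Typical use::

    from plgrouper import (
        load_ontology, load_mapping, load_grouper_definitions,
        compile_groupers, read_problem_list, organize_problem_list,
    )

    onto = load_ontology("edges.tsv", dialect="edge_list")
    groupers = compile_groupers(load_grouper_definitions("groupers.yaml"), onto)
    grouped = organize_problem_list(
        read_problem_list("problems.csv"), load_mapping("mapping.tsv"),
        groupers, onto,
    )
"""

from importlib import resources as _resources
from pathlib import Path

from .errors import (
    ConfigError,
    CycleError,
    DanglingParentError,
    EvaluationError,
    GrouperError,
    MappingError,
    OntologyError,
    PlgrouperError,
    ReconstructionError,
    UnknownConceptError,
)
from .ontology import Concept, Ontology, load_ontology
from .mapping import (
    MappingEntry,
    MappingTable,
    load_mapping,
    map_diagnosis,
    normalize_icd,
    save_mapping,
)
from .groupers import (
    OTHER_NAME,
    OTHER_RANK,
    SYSTEM_GROUPER_NAMES,
    CompiledGrouper,
    GroupedProblemList,
    GrouperAssignment,
    GrouperDefinition,
    OverlapReport,
    ProblemEntry,
    Section,
    classify_concept,
    compile_grouper,
    compile_groupers,
    grouped_to_dict,
    load_grouper_definitions,
    organize_problem_list,
    read_problem_list,
    save_grouper_definitions,
    validate_groupers,
    write_assignments_csv,
    write_grouped_json,
)
from .evaluation import (
    AdjudicationResult,
    AgreementResult,
    AssessmentCategory,
    ConfusionCounts,
    KappaResult,
    Metrics,
    ReconstructionResult,
    ReviewRecord,
    adjudicate,
    agreement,
    categorize,
    cohen_kappa,
    compute_metrics,
    reconstruct_counts,
    render_metrics,
    render_ratio,
    round_half_away,
    tally,
)
from .synthetic import (
    GoldLabel,
    SynthConfig,
    SyntheticBundle,
    SyntheticOntology,
    SyntheticStudy,
    generate_bundle,
    generate_groupers,
    generate_ontology,
    generate_problem_lists,
)

__version__ = "0.1.0"


def toy_fixture_dir() -> Path:
    """Directory holding the bundled toy ontology/mapping/problem fixture."""
    return Path(str(_resources.files("plgrouper").joinpath("data", "toy")))


__all__ = [name for name in dir() if not name.startswith("_")]
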