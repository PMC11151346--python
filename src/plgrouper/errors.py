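"""Exception hierarchy for plgrouper.

Everything raised on bad input derives from :class:`PlgrouperError`, so callers
(and the CLI) can catch one type and turn it into a clean exit.
"""


class PlgrouperError(ValueError):
    """Base class for all plgrouper errors."""


class OntologyError(PlgrouperError):
    """Malformed or inconsistent concept hierarchy."""


class CycleError(OntologyError):
    """The is-a relation contains a cycle (must be a DAG)."""


class DanglingParentError(OntologyError):
    """A concept references a parent id that does not exist."""


class UnknownConceptError(OntologyError):
    """Lookup of an id that is absent or inactive."""


class MappingError(PlgrouperError):
    """Malformed diagnosis-mapping table."""


class GrouperError(PlgrouperError):
    """Invalid grouper definition or compilation failure."""


class EvaluationError(PlgrouperError):
    """Inconsistent review/assessment input."""


class ReconstructionError(EvaluationError):
    """No confusion matrix is consistent with the stated marginals."""


class ConfigError(PlgrouperError):
    """Invalid run configuration."""
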