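"""Exception hierarchy.

Every error raised by the library derives from :class:`TaxoprovError`, so
callers (and the CLI) can catch one base class and map it to an exit code.
"""


class TaxoprovError(Exception):
    """Base class for all taxoprov errors."""


# --- model -----------------------------------------------------------------

class KindClashError(TaxoprovError):
    """An entity id is already bound to a different kind."""


class EmptyAttributionError(TaxoprovError):
    """An entity or statement was supplied with an empty attribution set."""


class DanglingEndpointError(TaxoprovError):
    """A statement references an entity id that is not in the graph."""


class KindConstraintError(TaxoprovError):
    """A statement violates the subject/object kind constraints of its
    predicate, or carries a frequency qualifier on a non-phenotype edge."""


class CycleError(TaxoprovError):
    """A sub-typing or group-membership edge would close a directed cycle."""


class InvalidGraphError(TaxoprovError):
    """An operation requiring a valid graph was given an invalid one."""

    def __init__(self, report, message: str = "graph failed validation"):
        self.report = report
        detail = "; ".join(
            f"{v.code}({','.join(v.subjects)})" for v in report.violations[:5]
        )
        super().__init__(f"{message}: {detail}")


class NotClassifiableError(TaxoprovError):
    """classify_node_kind was asked about a gene/phenotype/inheritance node."""


class UnknownEntityError(TaxoprovError):
    """An entity id does not exist in the graph."""


class WrongKindError(TaxoprovError):
    """An entity exists but has the wrong kind for the requested operation."""


class UnknownAgentError(TaxoprovError):
    """An agent id is not registered in the graph."""


class EmptyAgentSetError(TaxoprovError):
    """A provenance view was requested for an empty agent set."""


# --- source_io -------------------------------------------------------------

class SchemaError(TaxoprovError):
    """A source document does not conform to the JSON dialect."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class HeaderMismatchError(TaxoprovError):
    """An alignment TSV does not start with the fixed 6-column header."""


class UnknownDecisionError(TaxoprovError):
    """An alignment row carries a decision outside {GROUP, DISORDER, AUTO}."""


class NonFunctionalAlignmentError(TaxoprovError):
    """An id is aligned to two different counterparts in the same source."""


class DialectError(TaxoprovError):
    """Turtle input contains triples not covered by the serialization dialect."""


# --- merge -----------------------------------------------------------------

class UnknownAlignedIdError(TaxoprovError):
    """An alignment row references an id not declared by its source."""


class DuplicateLocalIdError(TaxoprovError):
    """Two sources with the same agent declare conflicting records for one id."""


class KindClashAcrossSourcesError(TaxoprovError):
    """An aligned cluster mixes irreconcilable kinds."""


class UnresolvableKindError(TaxoprovError):
    """resolve_kind had no decision, no agreement and no heuristic verdict."""


# --- fixtures --------------------------------------------------------------

class InfeasibleParamsError(TaxoprovError):
    """Fixture parameters are mutually inconsistent."""
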