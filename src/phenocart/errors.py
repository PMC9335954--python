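"""Exception hierarchy.

Every error the library raises derives from :class:`PhenocartError`, so the
CLI can map library failures to a user-error exit status and everything else
to an environment-error status.
"""


class PhenocartError(Exception):
    """Base class for all errors raised by this package."""


class OboParseError(PhenocartError):
    """Malformed OBO input (missing id, duplicate id, bad stanza)."""


class OntologyCycleError(OboParseError):
    """The is_a graph over non-obsolete terms contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("is_a cycle among non-obsolete terms: " + " -> ".join(self.cycle))


class TermLookupError(PhenocartError, LookupError):
    """A term id could not be resolved to a usable primary term."""


class ObsoleteTermError(TermLookupError):
    """An obsolete term was used where a current term is required."""

    def __init__(self, term_id: str, replacement: str | None = None):
        self.term_id = term_id
        self.replacement = replacement
        msg = f"term {term_id} is obsolete"
        if replacement:
            msg += f"; consider its replacement {replacement}"
        super().__init__(msg)


class GeneTableError(PhenocartError):
    """Malformed gene-association table row."""


class RecordSchemaError(PhenocartError):
    """A record payload is missing a required key or has the wrong shape."""


class RecordVersionError(RecordSchemaError):
    """A record payload declares an unsupported schema version."""


class StoreConflictError(PhenocartError):
    """Two writers tried to save the same record version for a patient."""


class StoreLookupError(PhenocartError, LookupError):
    """Unknown patient or record version in the store."""


class ValidationBlockedError(PhenocartError):
    """A cart with blocking validation issues was submitted for saving."""

    def __init__(self, issues):
        self.issues = list(issues)
        msgs = "; ".join(i.message for i in self.issues)
        super().__init__(f"cart has blocking validation issues: {msgs}")


class CorruptionError(PhenocartError):
    """A corruption op targets a nonexistent mention or invalid position."""


class FixtureError(PhenocartError):
    """Invalid parameters passed to a synthetic-data generator."""
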