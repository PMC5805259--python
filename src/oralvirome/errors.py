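"""Exception hierarchy."""


class OralviromeError(Exception):
    """Base class for all package errors."""


class HitTableParseError(OralviromeError):
    """A hit-table row is malformed (wrong column count, non-numeric field)."""


class ConfigurationError(OralviromeError):
    """Required configuration is missing or inconsistent (e.g. no read length)."""


class TaxonomyError(OralviromeError):
    """The taxonomy is structurally invalid (cycle, bad rank, dangling parent)."""


class UnknownSubjectError(OralviromeError):
    """An alignment subject is not present in the subject-to-taxon map."""


class AnnotationError(OralviromeError):
    """A subject lacks the viral-class annotation needed for partitioning."""


class ValidationError(OralviromeError):
    """An input value violates a documented contract."""
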