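"""Exception hierarchy shared across the package."""


class CrisprMemoryError(Exception):
    """Base class for all package errors."""


class ConfigError(CrisprMemoryError):
    """Malformed or out-of-range configuration."""


class ValidationError(CrisprMemoryError):
    """Invalid argument or parameter value."""


class MissingSequenceError(CrisprMemoryError):
    """A table references a sequence id absent from its FASTA companion."""


class DuplicateKeyError(CrisprMemoryError):
    """A primary key (array id, sequence id) occurs more than once."""


class ProvenanceError(CrisprMemoryError):
    """A contig lacks the subject/sample annotation required for local scans."""


class DependencyError(CrisprMemoryError):
    """A pipeline stage was requested before its upstream stage ran."""


class CoordinateError(CrisprMemoryError):
    """Coordinates fall outside the sequence they refer to."""


class DegenerateDataError(CrisprMemoryError):
    """Input data carries no information for the requested fit."""


class EmptyStateStringError(CrisprMemoryError):
    """An episode has no non-empty state to encode."""
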