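"""Exception hierarchy.

Every ingest/validation failure raises a distinct subclass so callers (and
tests) can tell a malformed file apart from a domain violation without
string-matching messages.
"""


class MegselectError(Exception):
    """Base class for all package errors."""


class InputFormatError(MegselectError, ValueError):
    """A file could not be parsed into the expected tabular layout."""


class MalformedHeaderError(InputFormatError):
    """Header row missing, empty, or lacking mandatory columns."""


class DuplicateIdentifierError(InputFormatError):
    """Gene or sample identifiers are not unique."""


class NonNumericValueError(InputFormatError):
    """An expression cell is missing or not a finite number."""


class EmptyInputError(InputFormatError):
    """A file or table contains no data rows."""


class DomainError(MegselectError, ValueError):
    """A value violates its domain (negative survival time, unknown stage...)."""


class AlignmentError(MegselectError, ValueError):
    """Expression and clinical tables share no samples."""


class PipelineError(MegselectError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
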