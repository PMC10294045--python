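"""Exception hierarchy.

Every error raised by the public API derives from :class:`HealthLitError`,
so callers (and the CLI) can distinguish usage problems (configuration,
resources) from processing problems (empty documents, bad report files).
"""

from __future__ import annotations


class HealthLitError(Exception):
    """Base class for all package errors."""


class InputEncodingError(HealthLitError):
    """Raised when input bytes cannot be decoded as UTF-8."""


class EmptyDocumentError(HealthLitError):
    """Raised when an assessment that needs content receives an empty document."""


class ConfigurationError(HealthLitError):
    """Invalid configuration: bad thresholds, unknown assessments, bad resources."""


class ExclusionLimitError(ConfigurationError):
    """More than the allowed number of excluded words (maximum 5)."""


class ResourceFormatError(ConfigurationError):
    """A lexicon/ruleset/abbreviation file is malformed.

    Carries the offending path and 1-based line number where available.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)


class ReportFormatError(HealthLitError):
    """A serialized report file is malformed or truncated."""

    def __init__(self, message: str, path: str | None = None):
        self.path = path
        super().__init__(message + (f" [{path}]" if path else ""))


class SchemaVersionError(ReportFormatError):
    """A serialized report or config declares an unsupported schema version."""


class FixtureSpecError(HealthLitError):
    """A synthetic-text fixture specification is internally impossible."""
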