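"""Exception hierarchy shared across pepx modules."""

from __future__ import annotations


class PepXError(Exception):
    """Base class for all pepx-specific errors."""


class ProteomeParseError(PepXError):
    """One or more FASTA records could not be parsed.

    Carries ``errors``: a list of ``(line_number, record_id, message)``
    tuples, one per offending record.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(
            f"line {ln} ({rid}): {msg}" for ln, rid, msg in self.errors
        )
        super().__init__(f"{len(self.errors)} malformed FASTA record(s): {lines}")


class IntegrityError(PepXError):
    """Duplicate identifiers or internally inconsistent inputs."""


class PeptideLengthError(PepXError, ValueError):
    """Query peptide length falls outside the indexed range."""


class PeptideValidationError(PepXError, ValueError):
    """Query peptide is not an uppercase amino-acid string."""


class TableParseError(PepXError):
    """A TPM table cell could not be interpreted.

    ``row`` and ``column`` name the offending cell (feature id and
    subtype/sample header).
    """

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        super().__init__(message)


class ConfigurationError(PepXError):
    """User-supplied configuration is inconsistent with the data."""


class CapacityError(PepXError):
    """The proteome cannot supply the requested number of decoys."""


class NoExpressionDataError(PepXError):
    """A peptide maps to the proteome but no source has expression data."""


class DegenerateDataError(PepXError):
    """Statistical test input is degenerate (e.g. all paired differences zero)."""


class UndefinedCorrelationError(PepXError):
    """Correlation undefined, e.g. one input vector is constant."""


class FixtureSpecError(PepXError):
    """A synthetic-fixture specification is invalid."""
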