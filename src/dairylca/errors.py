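"""Named exceptions raised across the pipeline."""

from __future__ import annotations


class DairyLCAError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DairyLCAError):
    """A domain object or input file violates a stated invariant.

    Carries the offending field paths in the message.
    """


class SchemaError(InvalidInputError):
    """A structured-text file is missing or has an unsupported schema version."""


class MissingFactorError(DairyLCAError):
    """A referenced (item, category) pair has no emission-factor row."""

    def __init__(self, item_key: str, category: str):
        self.item_key = item_key
        self.category = category
        super().__init__(f"no emission factor for item {item_key!r}, category {category!r}")


class DuplicateFactorError(DairyLCAError):
    """The emission-factor table contains a repeated (item, category) key."""


class AllocationCollapseError(DairyLCAError):
    """Biophysical allocation is undefined: 6.04 * Mmeat / Mmilk >= 1."""


class ZeroDivisionInputError(DairyLCAError):
    """A required denominator (trial milk yield, FPCM) is zero."""


class WindowMismatchError(DairyLCAError):
    """Paired trial records cover different lactation windows."""


class UnknownParameterError(DairyLCAError):
    """A sensitivity-analysis parameter name does not resolve."""


class EmptyReportError(DairyLCAError):
    """A comparison report with no categories cannot be rendered."""
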