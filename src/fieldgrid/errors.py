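"""Exception hierarchy shared by all fieldgrid modules."""

from __future__ import annotations


class FieldGridError(Exception):
    """Base class for all fieldgrid errors."""


class ConfigurationError(FieldGridError):
    """A trial configuration violates an invariant (bad grid, trait or barcode)."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class ValidationError(FieldGridError):
    """One or more raw values were rejected by trait validation.

    Carries the full per-value violation list so callers can report every
    offending input at once rather than failing on the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        detail = "; ".join(f"{v.raw!r}: {v.detail}" for v in self.violations)
        super().__init__(f"{len(self.violations)} invalid value(s): {detail}")


class NotFoundError(FieldGridError):
    """A barcode, cell or trait was looked up but does not exist in the trial."""


class GeometryError(FieldGridError):
    """Degenerate corner geometry or a point mapped to infinity."""


class UnsupportedTraitError(FieldGridError):
    """The requested analytic is undefined for this trait's data type."""


class PayloadError(FieldGridError):
    """A configuration payload could not be parsed as JSON or has foreign keys."""
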