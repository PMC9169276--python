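"""Type-driven parsing and restriction checking of raw text values.

Every raw input string maps to exactly one of: a typed value, or a
:class:`Violation` describing why it was rejected (totality — the validator
never raises on malformed input). Violations distinguish unparseable text
(PARSE), numbers outside a trait's inclusive range (RANGE), and strings that
are not members of a categorical trait's pre-defined pick list (CATEGORY).

Conventions, fixed so that exports are machine-stable:

* INT is strict: an optional leading ``-`` and digits only — no decimal
  point, no leading ``+``, no whitespace.
* FLOAT is permissive decimal notation, scientific notation included;
  NaN/infinity are rejected (they cannot satisfy a range).
* DATE is ISO 8601 extended ``YYYY-MM-DD``, a literal calendar date.
* CATEGORICAL matching is case-sensitive and exact: categories are
  pre-defined pick lists, not free input.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from datetime import date
from typing import Union

from .model import Trait, TraitType


class ViolationKind(enum.Enum):
    PARSE = "parse"
    RANGE = "range"
    CATEGORY = "category"


@dataclass(frozen=True)
class Violation:
    """A rejected raw value, with the rule it broke and a human-readable detail."""

    kind: ViolationKind
    raw: str
    detail: str


TypedValue = Union[int, float, date, str]
_INT_RE = re.compile(r"-?\d+\Z")
_FLOAT_RE = re.compile(r"[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?\Z")
_DATE_RE = re.compile(r"\d{4}-\d{2}-\d{2}\Z")


def parse_value(trait: Trait, raw: str) -> Union[TypedValue, Violation]:
    """Parse raw text into the trait's native type, or a PARSE violation."""
    if trait.dtype is TraitType.TEXT:
        return raw
    if trait.dtype is TraitType.INT:
        if _INT_RE.fullmatch(raw):
            return int(raw)
        return Violation(ViolationKind.PARSE, raw, "not a strict integer")
    if trait.dtype is TraitType.FLOAT:
        if _FLOAT_RE.fullmatch(raw):
            value = float(raw)
            if math.isfinite(value):
                return value
        return Violation(ViolationKind.PARSE, raw, "not a finite decimal number")
    if trait.dtype is TraitType.DATE:
        if _DATE_RE.fullmatch(raw):
            try:
                return date.fromisoformat(raw)
            except ValueError:
                pass
        return Violation(ViolationKind.PARSE, raw, "not an ISO 8601 date (YYYY-MM-DD)")
    if trait.dtype is TraitType.CATEGORICAL:
        if trait.categories and raw in trait.categories:
            return raw
        return Violation(
            ViolationKind.CATEGORY, raw, f"not one of {list(trait.categories or ())}"
        )
    raise AssertionError(f"unhandled trait type {trait.dtype}")  # pragma: no cover


def check_restrictions(trait: Trait, value: TypedValue) -> Union[None, Violation]:
    """Check an already-parsed value against the trait's restrictions.

    Numeric bounds are inclusive; a missing bound is unbounded. DATE and
    TEXT values always pass; categorical membership is (re)checked here so
    the function is total over parsed values.
    """
    if trait.dtype in (TraitType.INT, TraitType.FLOAT):
        raw = serialize_value(trait, value)
        if trait.min is not None and value < trait.min:
            return Violation(ViolationKind.RANGE, raw, f"{value} below minimum {trait.min}")
        if trait.max is not None and value > trait.max:
            return Violation(ViolationKind.RANGE, raw, f"{value} above maximum {trait.max}")
        return None
    if trait.dtype is TraitType.CATEGORICAL:
        if trait.categories and value in trait.categories:
            return None
        return Violation(
            ViolationKind.CATEGORY, str(value), f"not one of {list(trait.categories or ())}"
        )
    return None


def validate(trait: Trait, raw: str) -> Union[TypedValue, Violation]:
    """Parse then restriction-check in one step; the common entry point."""
    parsed = parse_value(trait, raw)
    if isinstance(parsed, Violation):
        return parsed
    violation = check_restrictions(trait, parsed)
    return parsed if violation is None else violation


def serialize_value(trait: Trait, value: TypedValue) -> str:
    """Render a typed value back to text such that re-validation is a fixed point.

    Floats use Python's shortest round-tripping repr, so ``42.5`` exports as
    ``"42.5"`` and parses back to exactly ``42.5``.
    """
    if trait.dtype is TraitType.INT:
        return str(int(value))
    if trait.dtype is TraitType.FLOAT:
        return repr(float(value))
    if trait.dtype is TraitType.DATE:
        return value.isoformat()
    return str(value)
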