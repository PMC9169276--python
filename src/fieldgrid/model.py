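"""Trial data model and state-mutating record operations.

A trial is a rows x cols grid of plots, each planted with one germplasm
entry (a genetically distinct line, possibly one replicate of several) and
scored for a declared list of traits. The model is value-semantic: every
operation returns a new :class:`TrialState` and never observably mutates its
argument, which keeps scoring histories easy to test and to undo.

Grid coordinates are 0-based ``(row, col)`` with row 0 the top row of the
field plan and col 0 the leftmost column.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError, NotFoundError

Cell = tuple[int, int]


class TraitType(enum.Enum):
    """Data type of a trait, driving input parsing and restriction checks."""

    INT = "int"
    FLOAT = "float"
    CATEGORICAL = "categorical"
    DATE = "date"
    TEXT = "text"


@dataclass(frozen=True)
class Trait:
    """A phenotypic character with its data type and input restrictions.

    Numeric traits may carry inclusive ``min``/``max`` range restrictions;
    categorical traits must pre-define their valid ``categories``. A trait
    flagged ``multi`` accepts repeated measurements per plot across the
    season (e.g. repeated yield picks); all others hold a single, replaceable
    measurement.
    """

    name: str
    dtype: TraitType
    min: Optional[float] = None
    max: Optional[float] = None
    categories: Optional[tuple[str, ...]] = None
    multi: bool = False

    def __post_init__(self):
        if not self.name:
            raise ConfigurationError("trait name must be non-empty", field="name")
        if self.categories is not None:
            object.__setattr__(self, "categories", tuple(self.categories))
        numeric = self.dtype in (TraitType.INT, TraitType.FLOAT)
        if (self.min is not None or self.max is not None) and not numeric:
            raise ConfigurationError(
                f"trait {self.name!r}: range restrictions only apply to numeric traits",
                field="min",
            )
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ConfigurationError(
                f"trait {self.name!r}: min {self.min} exceeds max {self.max}",
                field="min",
            )
        for bound, label in ((self.min, "min"), (self.max, "max")):
            if bound is not None and not math.isfinite(bound):
                raise ConfigurationError(
                    f"trait {self.name!r}: {label} must be finite", field=label
                )
        if self.dtype is TraitType.CATEGORICAL:
            if not self.categories:
                raise ConfigurationError(
                    f"categorical trait {self.name!r} must pre-define its categories",
                    field="categories",
                )
            if len(set(self.categories)) != len(self.categories):
                raise ConfigurationError(
                    f"trait {self.name!r}: categories must be unique",
                    field="categories",
                )
        elif self.categories is not None:
            raise ConfigurationError(
                f"trait {self.name!r}: categories only apply to categorical traits",
                field="categories",
            )


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self):
        object.__setattr__(self, "lat", float(self.lat))
        object.__setattr__(self, "lon", float(self.lon))
        if not (-90.0 <= self.lat <= 90.0):
            raise ConfigurationError(f"latitude {self.lat} outside [-90, 90]", field="lat")
        if not (-180.0 <= self.lon <= 180.0):
            raise ConfigurationError(f"longitude {self.lon} outside [-180, 180]", field="lon")


@dataclass(frozen=True)
class GeoQuad:
    """The four field-plan corner points, in TL, TR, BR, BL order."""

    corners: tuple[GeoPoint, GeoPoint, GeoPoint, GeoPoint]

    def __post_init__(self):
        object.__setattr__(self, "corners", tuple(self.corners))
        if len(self.corners) != 4:
            raise ConfigurationError("a corner quad requires exactly 4 points", field="corners")
        pts = [(p.lon, p.lat) for p in self.corners]
        if len(set(pts)) != 4:
            raise ConfigurationError("corner points must be pairwise distinct", field="corners")
        # reject any three collinear corners: they cannot bound a field
        for i in range(4):
            (x0, y0), (x1, y1), (x2, y2) = (pts[j] for j in range(4) if j != i)
            cross = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
            if abs(cross) < 1e-15:
                raise ConfigurationError(
                    "three corner points are collinear", field="corners"
                )


@dataclass(frozen=True)
class GermplasmEntry:
    """What is planted in one plot: identifier, optional replicate and barcode."""

    identifier: str
    rep: Optional[str] = None
    barcode: Optional[str] = None

    def __post_init__(self):
        if not self.identifier:
            raise ConfigurationError("germplasm identifier must be non-empty", field="identifier")


@dataclass(frozen=True)
class TrialConfig:
    """Immutable trial setup: name, grid, germplasm layout, trait schema, corners."""

    name: str
    rows: int
    cols: int
    germplasm: Mapping[Cell, GermplasmEntry]
    traits: tuple[Trait, ...]
    corners: Optional[GeoQuad] = None
    comment: Optional[str] = None

    def __post_init__(self):
        if not self.name:
            raise ConfigurationError("trial name must be non-empty", field="name")
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError(
                f"grid dimensions must be positive, got {self.rows}x{self.cols}",
                field="rows" if self.rows < 1 else "cols",
            )
        object.__setattr__(self, "germplasm", dict(self.germplasm))
        object.__setattr__(self, "traits", tuple(self.traits))
        expected = {(r, c) for r in range(self.rows) for c in range(self.cols)}
        if set(self.germplasm) != expected:
            missing = expected - set(self.germplasm)
            extra = set(self.germplasm) - expected
            what = f"missing cells {sorted(missing)[:3]}" if missing else f"cells outside grid {sorted(extra)[:3]}"
            raise ConfigurationError(f"germplasm layout incomplete: {what}", field="germplasm")
        barcodes = [e.barcode for e in self.germplasm.values() if e.barcode is not None]
        if len(set(barcodes)) != len(barcodes):
            dup = sorted(b for b in set(barcodes) if barcodes.count(b) > 1)
            raise ConfigurationError(f"duplicate barcode(s): {dup}", field="germplasm")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            dup = sorted(n for n in set(names) if names.count(n) > 1)
            raise ConfigurationError(f"duplicate trait name(s): {dup}", field="traits")

    def trait(self, name: str) -> Trait:
        for t in self.traits:
            if t.name == name:
                return t
        raise NotFoundError(f"trait {name!r} not defined in trial {self.name!r}")

    def cells(self):
        """All grid cells in row-major order."""
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]


def _as_utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        raise ConfigurationError("timestamps must be timezone-aware", field="timestamp")
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class Measurement:
    """One recording session: typed value(s), UTC timestamp, optional GPS fix."""

    values: tuple
    timestamp: datetime
    location: Optional[GeoPoint] = None

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(self.values))
        if not self.values:
            raise ConfigurationError("a measurement must carry at least one value", field="values")
        object.__setattr__(self, "timestamp", _as_utc(self.timestamp))


@dataclass(frozen=True)
class Comment:
    text: str
    timestamp: datetime

    def __post_init__(self):
        if not self.text:
            raise ConfigurationError("comment text must be non-empty", field="text")
        object.__setattr__(self, "timestamp", _as_utc(self.timestamp))


@dataclass(frozen=True)
class PlotRecord:
    """Everything recorded against one plot."""

    measurements: Mapping[str, tuple[Measurement, ...]] = field(default_factory=dict)
    comments: tuple[Comment, ...] = ()
    bookmarked: bool = False
    images: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "measurements", {k: tuple(v) for k, v in dict(self.measurements).items()}
        )
        object.__setattr__(self, "comments", tuple(self.comments))
        object.__setattr__(self, "images", tuple(self.images))


@dataclass(frozen=True)
class TrialState:
    """A trial configuration plus all data recorded against it."""

    config: TrialConfig
    records: Mapping[Cell, PlotRecord]

    def __post_init__(self):
        object.__setattr__(self, "records", dict(self.records))
        if set(self.records) - set(self.config.germplasm):
            raise ConfigurationError("records exist for cells outside the grid", field="records")

    def record(self, cell: Cell) -> PlotRecord:
        _require_cell(self.config, cell)
        return self.records[cell]


def _require_cell(config: TrialConfig, cell: Cell) -> None:
    r, c = cell
    if not (0 <= r < config.rows and 0 <= c < config.cols):
        raise NotFoundError(
            f"cell {cell} outside the {config.rows}x{config.cols} grid"
        )


def create_trial(config: TrialConfig) -> TrialState:
    """Return a fresh state with one empty plot record per grid cell."""
    return TrialState(config=config, records={cell: PlotRecord() for cell in config.cells()})


def resolve_barcode(state: TrialState, code: str) -> Cell:
    """Find the unique plot whose germplasm entry carries this barcode."""
    for cell, entry in state.config.germplasm.items():
        if entry.barcode is not None and entry.barcode == code:
            return cell
    raise NotFoundError(f"no plot carries barcode {code!r}")


def add_measurement(
    state: TrialState,
    cell: Cell,
    trait_name: str,
    raw_values: Sequence[str],
    timestamp: datetime,
    location: Optional[GeoPoint] = None,
) -> TrialState:
    """Validate raw text values against the trait and store them.

    All values are parsed and restriction-checked before anything is stored;
    a single bad value rejects the whole call with the full violation list.
    Single-measurement traits are replaced on re-entry (correction workflow);
    multi-measurement traits append a new recording session.
    """
    from . import validation  # deferred: validation depends on Trait

    _require_cell(state.config, cell)
    trait = state.config.trait(trait_name)
    if not raw_values:
        raise ConfigurationError("no values supplied", field="values")
    if not trait.multi and len(raw_values) > 1:
        raise ConfigurationError(
            f"trait {trait_name!r} is single-measurement; got {len(raw_values)} values",
            field="values",
        )
    parsed, violations = [], []
    for raw in raw_values:
        result = validation.validate(trait, raw)
        if isinstance(result, validation.Violation):
            violations.append(result)
        else:
            parsed.append(result)
    if violations:
        from .errors import ValidationError

        raise ValidationError(violations)

    measurement = Measurement(values=tuple(parsed), timestamp=timestamp, location=location)
    old = state.records[cell]
    existing = old.measurements.get(trait_name, ())
    new_list = existing + (measurement,) if trait.multi else (measurement,)
    new_record = dataclasses.replace(
        old, measurements={**old.measurements, trait_name: new_list}
    )
    return TrialState(state.config, {**state.records, cell: new_record})


def add_comment(state: TrialState, cell: Cell, text: str, timestamp: datetime) -> TrialState:
    """Append a free-text comment (with timestamp) to a plot."""
    _require_cell(state.config, cell)
    old = state.records[cell]
    new_record = dataclasses.replace(old, comments=old.comments + (Comment(text, timestamp),))
    return TrialState(state.config, {**state.records, cell: new_record})


def toggle_bookmark(state: TrialState, cell: Cell) -> TrialState:
    """Invert a plot's bookmark flag."""
    _require_cell(state.config, cell)
    old = state.records[cell]
    new_record = dataclasses.replace(old, bookmarked=not old.bookmarked)
    return TrialState(state.config, {**state.records, cell: new_record})


def tag_image(state: TrialState, cell: Cell, filename: str) -> TrialState:
    """Attach an image filename to a plot."""
    _require_cell(state.config, cell)
    if not filename:
        raise ConfigurationError("image filename must be non-empty", field="filename")
    old = state.records[cell]
    new_record = dataclasses.replace(old, images=old.images + (filename,))
    return TrialState(state.config, {**state.records, cell: new_record})


def reset_trial(state: TrialState) -> TrialState:
    """Clear all recorded data, keeping the configuration.

    Supports season-long repeated scoring workflows where data is exported
    and the trial reset between scoring passes.
    """
    return create_trial(state.config)
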