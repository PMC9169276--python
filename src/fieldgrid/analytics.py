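"""Scoring-progress and trait-distribution analytics.

These functions back the field-plan overview a scorer relies on in the
field: which plots still need scoring for which traits, how coverage grew
over the season, how trait values distribute, and where in the field high
or low values cluster (a heat map can expose soil gradients or edge
effects). Everything returns plain matrices, series and summary records;
chart rendering is a caller concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Optional, Union

import numpy as np

from .errors import UnsupportedTraitError
from .model import Trait, TraitType, TrialState

_EPOCH = date(1970, 1, 1)


@dataclass(frozen=True)
class TraitProgress:
    trait: str
    scored_plots: int
    total_plots: int

    @property
    def fraction(self) -> float:
        return self.scored_plots / self.total_plots


@dataclass(frozen=True)
class TimelineSeries:
    """Cumulative scored-plot fraction of one trait per UTC calendar date."""

    trait: str
    points: tuple[tuple[date, float], ...]


@dataclass(frozen=True)
class TraitSummary:
    """Five-number summary + mean for numeric/date traits; counts for categorical.

    Date values are summarized on the scale of days since 1970-01-01. An
    empty summary (no data yet) has ``n == 0`` and ``None`` statistics.
    """

    trait: str
    n: int
    min: Optional[float] = None
    q1: Optional[float] = None
    median: Optional[float] = None
    q3: Optional[float] = None
    max: Optional[float] = None
    mean: Optional[float] = None
    counts: Optional[dict[str, int]] = None

    @property
    def empty(self) -> bool:
        return self.n == 0


def cell_trait_flags(state: TrialState) -> list[list[set[str]]]:
    """Per-cell sets of trait names with at least one measurement (the colored dots)."""
    config = state.config
    flags = [[set() for _ in range(config.cols)] for _ in range(config.rows)]
    for (r, c), record in state.records.items():
        for name, measurements in record.measurements.items():
            if measurements:
                flags[r][c].add(name)
    return flags


def _scored_cells(state: TrialState, trait_name: str) -> list[tuple[int, int]]:
    return [
        cell
        for cell, record in state.records.items()
        if record.measurements.get(trait_name)
    ]


def progress_by_trait(state: TrialState) -> list[TraitProgress]:
    """Scored-plot fraction for every trait, in trait-schema order."""
    total = state.config.rows * state.config.cols
    return [
        TraitProgress(t.name, len(_scored_cells(state, t.name)), total)
        for t in state.config.traits
    ]


def progress_by_axis(state: TrialState, trait_name: str) -> tuple[list[int], list[int]]:
    """Counts of scored plots per row and per column for one trait."""
    config = state.config
    config.trait(trait_name)  # raises NotFoundError on unknown trait
    row_counts = [0] * config.rows
    col_counts = [0] * config.cols
    for r, c in _scored_cells(state, trait_name):
        row_counts[r] += 1
        col_counts[c] += 1
    return row_counts, col_counts


def timeline(state: TrialState) -> list[TimelineSeries]:
    """Cumulative percentage-of-plots-scored series per trait.

    The x-axis is the set of UTC calendar dates on which any measurement was
    recorded (shared across traits, so temporal relationships between traits
    are comparable). A plot counts as scored for a trait from the date of
    its FIRST measurement of that trait; later re-scores do not move the
    series — the chart measures coverage progress, not edits.
    """
    config = state.config
    total = config.rows * config.cols
    all_dates: set[date] = set()
    first_date: dict[str, list[date]] = {t.name: [] for t in config.traits}
    for record in state.records.values():
        for name, measurements in record.measurements.items():
            if not measurements:
                continue
            dates = [m.timestamp.date() for m in measurements]
            all_dates.update(dates)
            first_date[name].append(min(dates))
    axis = sorted(all_dates)
    series = []
    for t in config.traits:
        firsts = sorted(first_date[t.name])
        points = []
        for d in axis:
            scored = sum(1 for f in firsts if f <= d)
            points.append((d, scored / total))
        series.append(TimelineSeries(t.name, tuple(points)))
    return series


def _numeric_values(state: TrialState, trait: Trait) -> list[float]:
    values: list[float] = []
    for record in state.records.values():
        for m in record.measurements.get(trait.name, ()):
            for v in m.values:
                values.append(_as_number(trait, v))
    return values


def _as_number(trait: Trait, value) -> float:
    if trait.dtype is TraitType.DATE:
        return float((value - _EPOCH).days)
    return float(value)


def trait_summary(state: TrialState, trait_name: str) -> TraitSummary:
    """Distribution summary of all stored values of one trait.

    Multi-measurement traits contribute every stored value. Quartiles use
    linear interpolation between order statistics (numpy's default, R
    type 7). Categorical summaries count every pre-defined category,
    including those never recorded. Free-text traits have no meaningful
    distribution and are rejected.
    """
    trait = state.config.trait(trait_name)
    if trait.dtype is TraitType.TEXT:
        raise UnsupportedTraitError(f"trait {trait_name!r}: free-text traits are not summarizable")
    if trait.dtype is TraitType.CATEGORICAL:
        counts = {c: 0 for c in trait.categories or ()}
        n = 0
        for record in state.records.values():
            for m in record.measurements.get(trait_name, ()):
                for v in m.values:
                    counts[v] += 1
                    n += 1
        return TraitSummary(trait=trait_name, n=n, counts=counts)
    values = _numeric_values(state, trait)
    if not values:
        return TraitSummary(trait=trait_name, n=0)
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return TraitSummary(
        trait=trait_name,
        n=arr.size,
        min=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(arr.max()),
        mean=float(arr.mean()),
    )


def heatmap_matrix(
    state: TrialState, trait_name: str, agg: str = "latest"
) -> list[list[Optional[float]]]:
    """Rows x cols matrix of one trait's current value per plot.

    Entries hold the most recent measurement's value (``agg="latest"``,
    default — the "current state" field view) or, for numeric traits of
    multi-measurement design, the mean of all values (``agg="mean"``).
    Dates are encoded as days since 1970-01-01 and categories as their index
    in the pre-defined category list; unscored plots are ``None``. Free-text
    traits have no value scale and are rejected.
    """
    config = state.config
    trait = config.trait(trait_name)
    if trait.dtype is TraitType.TEXT:
        raise UnsupportedTraitError(f"trait {trait_name!r}: free-text traits have no heat-map scale")
    if agg not in ("latest", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")

    def encode(v) -> float:
        if trait.dtype is TraitType.CATEGORICAL:
            return float((trait.categories or ()).index(v))
        return _as_number(trait, v)

    matrix: list[list[Optional[float]]] = [
        [None] * config.cols for _ in range(config.rows)
    ]
    for (r, c), record in state.records.items():
        measurements = record.measurements.get(trait_name, ())
        if not measurements:
            continue
        if agg == "mean":
            vals = [encode(v) for m in measurements for v in m.values]
            matrix[r][c] = float(np.mean(vals))
        else:
            latest = max(measurements, key=lambda m: m.timestamp)
            matrix[r][c] = encode(latest.values[-1])
    return matrix


def scatter_pairs(
    state: TrialState, trait_a: str, trait_b: str
) -> list[tuple[float, float]]:
    """Paired per-plot values of two traits (heat-map encoding) for scatter export.

    Only plots scored for both traits contribute, using each trait's latest
    value.
    """
    ma = heatmap_matrix(state, trait_a)
    mb = heatmap_matrix(state, trait_b)
    return [
        (ma[r][c], mb[r][c])
        for r in range(state.config.rows)
        for c in range(state.config.cols)
        if ma[r][c] is not None and mb[r][c] is not None
    ]
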