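"""Synthetic trial configurations and scoring histories.

Every other module is testable without external data: this module builds
realistic trial setups (germplasm layouts, typed traits with valid
restrictions, a rectangular corner quad at a fixed Scottish field-site
anchor) and simulated scoring seasons (per-trait plot coverage, timestamps
spread over working days, GPS fixes at plot centers with Gaussian jitter
emulating consumer GPS error).

Output is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Mapping, Optional

import numpy as np

from . import model
from .model import (
    GeoPoint,
    GeoQuad,
    GermplasmEntry,
    Trait,
    TraitType,
    TrialConfig,
    TrialState,
)
from .validation import serialize_value

#: Anchor of the synthetic field site (eastern Scotland, arable land).
ANCHOR = GeoPoint(lat=56.4567, lon=-3.0695)

#: Nominal plot pitch in metres used to size the synthetic corner quad.
PLOT_PITCH_M = 1.5

_M_PER_DEG_LAT = 111_320.0

_TRAIT_NAMES = {
    TraitType.FLOAT: ("Plant height", "Yield", "Thousand grain weight", "Canopy cover"),
    TraitType.INT: ("Tiller count", "Ear count", "Lodging score"),
    TraitType.CATEGORICAL: ("Growth habit", "Awn type", "Disease presence"),
    TraitType.DATE: ("Heading date", "Emergence date", "Maturity date"),
    TraitType.TEXT: ("Notes", "Observations"),
}

_CATEGORY_POOLS = (
    ("erect", "intermediate", "prostrate"),
    ("awned", "awnless"),
    ("absent", "mild", "severe"),
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic trial and its simulated scoring season.

    Defaults describe a small cereal trial: a 6x8 grid (48 plots), two
    numeric traits, one integer, one categorical and one date trait, scored
    to 80% coverage over a 5-day scoring window with 2 m GPS noise.
    """

    rows: int = 6
    cols: int = 8
    trait_counts: Mapping[TraitType, int] = field(
        default_factory=lambda: {
            TraitType.FLOAT: 2,
            TraitType.INT: 1,
            TraitType.CATEGORICAL: 1,
            TraitType.DATE: 1,
        }
    )
    scoring_days: int = 5
    coverage: float = 0.8
    gps_noise_m: float = 2.0
    with_corners: bool = True
    multi_fraction: float = 0.25
    start_date: date = date(2022, 6, 6)
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")
        if self.scoring_days < 1:
            raise ValueError("scoring_days must be positive")
        if self.gps_noise_m < 0:
            raise ValueError("gps_noise_m must be non-negative")


def synth_quad(rows: int, cols: int, anchor: GeoPoint = ANCHOR) -> GeoQuad:
    """Axis-aligned rectangular corner quad sized to the grid at the anchor."""
    height_m = rows * PLOT_PITCH_M
    width_m = cols * PLOT_PITCH_M
    dlat = height_m / _M_PER_DEG_LAT
    dlon = width_m / (_M_PER_DEG_LAT * math.cos(math.radians(anchor.lat)))
    tl = GeoPoint(lat=anchor.lat, lon=anchor.lon)
    tr = GeoPoint(lat=anchor.lat, lon=anchor.lon + dlon)
    br = GeoPoint(lat=anchor.lat - dlat, lon=anchor.lon + dlon)
    bl = GeoPoint(lat=anchor.lat - dlat, lon=anchor.lon)
    return GeoQuad((tl, tr, br, bl))


def synth_config(spec: SynthSpec) -> TrialConfig:
    """Deterministic synthetic trial configuration for a spec."""
    rng = np.random.default_rng(spec.seed)
    germplasm = {}
    idx = 1
    for r in range(spec.rows):
        for c in range(spec.cols):
            germplasm[(r, c)] = GermplasmEntry(
                identifier=f"G-{idx:04d}", rep="1", barcode=f"B-{idx:04d}"
            )
            idx += 1
    traits = []
    cat_pool = 0
    for dtype in (
        TraitType.FLOAT,
        TraitType.INT,
        TraitType.CATEGORICAL,
        TraitType.DATE,
        TraitType.TEXT,
    ):
        count = spec.trait_counts.get(dtype, 0)
        names = _TRAIT_NAMES[dtype]
        for i in range(count):
            name = names[i] if i < len(names) else f"{names[0]} {i + 1}"
            kwargs = {}
            if dtype in (TraitType.INT, TraitType.FLOAT):
                lo = float(rng.integers(0, 50))
                hi = lo + float(rng.integers(10, 200))
                if dtype is TraitType.INT:
                    lo, hi = int(lo), int(hi)
                kwargs = {"min": lo, "max": hi}
            elif dtype is TraitType.CATEGORICAL:
                kwargs = {"categories": _CATEGORY_POOLS[cat_pool % len(_CATEGORY_POOLS)]}
                cat_pool += 1
            multi = dtype in (TraitType.INT, TraitType.FLOAT) and bool(
                rng.random() < spec.multi_fraction
            )
            traits.append(Trait(name=name, dtype=dtype, multi=multi, **kwargs))
    corners = synth_quad(spec.rows, spec.cols) if spec.with_corners else None
    return TrialConfig(
        name=f"Synthetic trial {spec.seed}",
        rows=spec.rows,
        cols=spec.cols,
        germplasm=germplasm,
        traits=tuple(traits),
        corners=corners,
        comment="synthetic fixture",
    )


def _jitter(rng: np.random.Generator, point: GeoPoint, sd_m: float) -> GeoPoint:
    if sd_m == 0:
        return point
    dn, de = rng.normal(0.0, sd_m, size=2)
    lat = point.lat + dn / _M_PER_DEG_LAT
    lon = point.lon + de / (_M_PER_DEG_LAT * math.cos(math.radians(point.lat)))
    return GeoPoint(lat=lat, lon=lon)


def _synth_raw(rng: np.random.Generator, trait: Trait, spec: SynthSpec) -> str:
    """One valid raw text value for a trait."""
    if trait.dtype is TraitType.INT:
        return str(int(rng.integers(int(trait.min), int(trait.max) + 1)))
    if trait.dtype is TraitType.FLOAT:
        value = round(float(rng.uniform(trait.min, trait.max)), 2)
        value = min(max(value, trait.min), trait.max)
        return serialize_value(trait, value)
    if trait.dtype is TraitType.CATEGORICAL:
        return str(rng.choice(list(trait.categories)))
    if trait.dtype is TraitType.DATE:
        offset = int(rng.integers(0, spec.scoring_days))
        return (spec.start_date + timedelta(days=offset)).isoformat()
    words = ("healthy", "lodging observed", "bird damage", "uneven emergence")
    return str(rng.choice(words))


def synth_state(config: TrialConfig, spec: SynthSpec) -> TrialState:
    """Simulate a scoring season over a trial.

    Per trait, a uniformly random subset of ``round(coverage * plots)``
    plots receives a valid in-range value; timestamps fall uniformly within
    08:00-18:00 UTC on a random scoring day; GPS fixes sit at plot centers
    plus isotropic Gaussian jitter of ``gps_noise_m`` metres (corners
    permitting). Multi-measurement traits receive one or two recording
    sessions per scored plot. All data passes through the same validation
    path as hand-entered values.
    """
    from .geo import cell_center, fit_projection

    rng = np.random.default_rng(spec.seed + 1)
    proj = fit_projection(config.corners) if config.corners is not None else None
    cells = config.cells()
    n_scored = round(spec.coverage * len(cells))
    state = model.create_trial(config)
    for trait in config.traits:
        chosen = rng.choice(len(cells), size=n_scored, replace=False)
        for i in sorted(int(j) for j in chosen):
            cell = cells[i]
            sessions = 1 + int(trait.multi and rng.random() < 0.5)
            for _ in range(sessions):
                day = int(rng.integers(0, spec.scoring_days))
                seconds = int(rng.integers(8 * 3600, 18 * 3600))
                ts = datetime.combine(
                    spec.start_date + timedelta(days=day),
                    datetime.min.time(),
                    tzinfo=timezone.utc,
                ) + timedelta(seconds=seconds)
                location: Optional[GeoPoint] = None
                if proj is not None:
                    center = cell_center(proj, cell[0], cell[1], config.rows, config.cols)
                    location = _jitter(rng, center, spec.gps_noise_m)
                state = model.add_measurement(
                    state, cell, trait.name, [_synth_raw(rng, trait, spec)], ts, location
                )
    return state


def synth_trial(spec: SynthSpec) -> TrialState:
    """Convenience: configuration plus simulated scoring history in one call."""
    config = synth_config(spec)
    return synth_state(config, spec)
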