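"""Shared fixtures and random-object generators for the test suite."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from fieldgrid.model import (
    GeoPoint,
    GeoQuad,
    GermplasmEntry,
    Trait,
    TraitType,
    TrialConfig,
    create_trial,
)

UTC = timezone.utc


def ts(*args) -> datetime:
    """Shorthand for a UTC datetime."""
    return datetime(*args, tzinfo=UTC)


def make_germplasm(rows: int, cols: int, barcodes: bool = True):
    return {
        (r, c): GermplasmEntry(
            identifier=f"G-{r * cols + c + 1:04d}",
            rep="1",
            barcode=f"B-{r * cols + c + 1:04d}" if barcodes else None,
        )
        for r in range(rows)
        for c in range(cols)
    }


STANDARD_TRAITS = (
    Trait("Plant height", TraitType.FLOAT, min=0, max=200),
    Trait("Tiller count", TraitType.INT, min=1, max=30),
    Trait("Growth habit", TraitType.CATEGORICAL, categories=("erect", "intermediate", "prostrate")),
    Trait("Heading date", TraitType.DATE),
    Trait("Notes", TraitType.TEXT),
    Trait("Yield", TraitType.FLOAT, min=0, max=5000, multi=True),
)


@pytest.fixture
def config_2x3() -> TrialConfig:
    return TrialConfig(
        name="Barley pilot",
        rows=2,
        cols=3,
        germplasm=make_germplasm(2, 3),
        traits=STANDARD_TRAITS,
    )


@pytest.fixture
def state_2x3(config_2x3):
    return create_trial(config_2x3)


def unit_square_quad() -> GeoQuad:
    """The quad whose fitted projection is the identity on (lon, lat)."""
    return GeoQuad(
        (
            GeoPoint(lat=0, lon=0),
            GeoPoint(lat=0, lon=1),
            GeoPoint(lat=1, lon=1),
            GeoPoint(lat=1, lon=0),
        )
    )


def random_quad(rng: np.random.Generator) -> GeoQuad:
    """A random strictly convex field-corner quadrilateral.

    Built as a small (~100-500 m) rectangle at a random mid-latitude site
    with corner perturbations under a quarter of the side length, which
    preserves convexity while exercising genuinely projective (non-affine)
    geometry.
    """
    lat0 = float(rng.uniform(-60, 60))
    lon0 = float(rng.uniform(-179, 179))
    size = float(rng.uniform(0.001, 0.005))
    base = [(0.0, 0.0), (size, 0.0), (size, -size), (0.0, -size)]  # TL TR BR BL
    jitter = rng.uniform(-0.24 * size, 0.24 * size, size=(4, 2))
    corners = tuple(
        GeoPoint(lat=lat0 + dy + float(j[1]), lon=lon0 + dx + float(j[0]))
        for (dx, dy), j in zip(base, jitter)
    )
    return GeoQuad(corners)


def random_config(rng: np.random.Generator, max_dim: int = 4) -> TrialConfig:
    """A random small but fully valid trial configuration."""
    rows = int(rng.integers(1, max_dim + 1))
    cols = int(rng.integers(1, max_dim + 1))
    germplasm = {}
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c + 1
            germplasm[(r, c)] = GermplasmEntry(
                identifier=f"G-{i:04d}",
                rep=str(int(rng.integers(1, 4))) if rng.random() < 0.5 else None,
                barcode=f"B-{i:04d}" if rng.random() < 0.7 else None,
            )
    traits = []
    n_traits = int(rng.integers(1, 5))
    for i in range(n_traits):
        dtype = list(TraitType)[int(rng.integers(0, 5))]
        kwargs = {}
        if dtype in (TraitType.INT, TraitType.FLOAT):
            if rng.random() < 0.7:
                lo = float(rng.integers(-20, 20))
                kwargs["min"] = int(lo) if dtype is TraitType.INT else lo
                hi = lo + float(rng.integers(1, 100))
                kwargs["max"] = int(hi) if dtype is TraitType.INT else hi
        elif dtype is TraitType.CATEGORICAL:
            n_cat = int(rng.integers(2, 5))
            kwargs["categories"] = tuple(f"cat{j}" for j in range(n_cat))
        traits.append(
            Trait(
                name=f"trait-{i}",
                dtype=dtype,
                multi=bool(rng.random() < 0.3) if dtype is not TraitType.TEXT else False,
                **kwargs,
            )
        )
    corners = random_quad(rng) if rng.random() < 0.5 else None
    return TrialConfig(
        name=f"random-{rng.integers(1_000_000)}",
        rows=rows,
        cols=cols,
        germplasm=germplasm,
        traits=tuple(traits),
        corners=corners,
        comment="fuzz" if rng.random() < 0.3 else None,
    )
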