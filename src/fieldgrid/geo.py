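"""Georeferencing: the grid-to-earth perspective projection and GPS helpers.

A trial whose four field-plan corners have been surveyed (or picked off a
map) is tied to the earth through a planar projective transformation
(homography): the unit square in normalized grid coordinates — ``u`` across
columns, ``v`` down rows, both in ``[0, 1]`` — maps onto the corner
quadrilateral in (lon, lat) degrees. The 8 free parameters are recovered
exactly from the four corner correspondences by the standard 8x8 linear
solve with the bottom-right matrix entry pinned to 1.

Longitude/latitude degrees are treated directly as planar coordinates. For
field trials spanning tens to a few hundred metres the planar approximation
error is orders of magnitude below consumer GPS noise; the simplification
breaks down only for "fields" spanning more than ~0.1 degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence, Union

import numpy as np

from .errors import GeometryError, NotFoundError
from .model import Cell, GeoPoint, GeoQuad, TrialState

EARTH_RADIUS_M = 6_371_000.0

#: Sentinel returned by :func:`geo_to_cell` for fixes outside the trial.
OUTSIDE = "OUTSIDE"

_EDGE_EPS = 1e-9  # tolerance absorbing the far grid boundary into the last cell


@dataclass(frozen=True)
class PlotProjection:
    """Fitted homography between normalized grid coordinates and (lon, lat)."""

    H: np.ndarray
    Hinv: np.ndarray


@dataclass(frozen=True)
class PhotoMeta:
    """Metadata of one photograph awaiting assignment to a plot."""

    filename: str
    timestamp: Optional[datetime] = None
    location: Optional[GeoPoint] = None

    def __post_init__(self):
        if not self.filename:
            raise ValueError("photo filename must be non-empty")


def fit_projection(quad: GeoQuad) -> PlotProjection:
    """Fit the projective transform sending the unit square onto the corner quad.

    Correspondences: (u,v) = (0,0) -> TL, (1,0) -> TR, (1,1) -> BR,
    (0,1) -> BL. Raises :class:`GeometryError` if the corners are degenerate
    (the linear system is singular).
    """
    tl, tr, br, bl = quad.corners
    src = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    dst = [(p.lon, p.lat) for p in (tl, tr, br, bl)]

    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((u, v), (x, y)) in enumerate(zip(src, dst)):
        A[2 * i] = [u, v, 1, 0, 0, 0, -u * x, -v * x]
        b[2 * i] = x
        A[2 * i + 1] = [0, 0, 0, u, v, 1, -u * y, -v * y]
        b[2 * i + 1] = y
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise GeometryError(f"degenerate corner quadrilateral: {exc}") from exc
    H = np.append(h, 1.0).reshape(3, 3)
    if abs(np.linalg.det(H)) < 1e-30:
        raise GeometryError("corner quadrilateral yields a singular projection")
    Hinv = np.linalg.inv(H)
    H.setflags(write=False)
    Hinv.setflags(write=False)
    return PlotProjection(H=H, Hinv=Hinv)


def _apply(M: np.ndarray, x: float, y: float) -> tuple[float, float]:
    hx, hy, w = M @ (x, y, 1.0)
    if abs(w) < 1e-15:
        raise GeometryError(f"point ({x}, {y}) maps to infinity")
    return hx / w, hy / w


def grid_to_geo(proj: PlotProjection, u: float, v: float) -> GeoPoint:
    """Map a normalized grid coordinate to earth (extrapolation allowed)."""
    lon, lat = _apply(proj.H, u, v)
    return GeoPoint(lat=lat, lon=lon)


def geo_to_grid(proj: PlotProjection, point: GeoPoint) -> tuple[float, float]:
    """Inverse map: earth position to normalized grid (u, v)."""
    return _apply(proj.Hinv, point.lon, point.lat)


def _require_cell(row: int, col: int, rows: int, cols: int) -> None:
    if not (0 <= row < rows and 0 <= col < cols):
        raise NotFoundError(f"cell ({row}, {col}) outside the {rows}x{cols} grid")


def cell_center(proj: PlotProjection, row: int, col: int, rows: int, cols: int) -> GeoPoint:
    """Earth position of a plot's center."""
    _require_cell(row, col, rows, cols)
    return grid_to_geo(proj, (col + 0.5) / cols, (row + 0.5) / rows)


def cell_polygon(
    proj: PlotProjection, row: int, col: int, rows: int, cols: int
) -> tuple[GeoPoint, GeoPoint, GeoPoint, GeoPoint]:
    """Earth positions of a plot's four corners, TL/TR/BR/BL order."""
    _require_cell(row, col, rows, cols)
    u0, u1 = col / cols, (col + 1) / cols
    v0, v1 = row / rows, (row + 1) / rows
    return (
        grid_to_geo(proj, u0, v0),
        grid_to_geo(proj, u1, v0),
        grid_to_geo(proj, u1, v1),
        grid_to_geo(proj, u0, v1),
    )


def geo_to_cell(
    proj: PlotProjection, point: GeoPoint, rows: int, cols: int
) -> Union[Cell, str]:
    """Resolve a GPS fix to the plot it falls in, or :data:`OUTSIDE`.

    Cells are half-open intervals ``[i/n, (i+1)/n)`` in each axis so every
    interior point belongs to exactly one cell; the far boundary (u or v
    exactly 1, within a 1e-9 tolerance) is absorbed into the last cell.
    """
    u, v = geo_to_grid(proj, point)
    if u < -_EDGE_EPS or u > 1.0 + _EDGE_EPS or v < -_EDGE_EPS or v > 1.0 + _EDGE_EPS:
        return OUTSIDE
    col = min(int(max(u, 0.0) * cols), cols - 1)
    row = min(int(max(v, 0.0) * rows), rows - 1)
    return (row, col)


def haversine(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in metres (spherical earth, radius 6 371 000 m)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (a.lat, a.lon, b.lat, b.lon))
    s = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(s)))


def match_photos(
    state: TrialState,
    photos: Sequence[PhotoMeta],
    max_dist_m: float = 25.0,
    max_dt_s: float = 300.0,
) -> dict[str, Union[Cell, str]]:
    """Assign photographs back to plots after the fact.

    Two-stage criterion per photo: (1) if the photo carries a GPS fix and the
    trial has surveyed corners, take the plot the fix falls in, or the
    nearest plot center within ``max_dist_m``; failing that, (2) take the
    plot holding the measurement whose timestamp is closest to the photo's,
    within ``max_dt_s``. Ties break to the smaller (row, col). Photos that
    match neither way map to ``"UNMATCHED"``.
    """
    config = state.config
    proj = fit_projection(config.corners) if config.corners is not None else None
    results: dict[str, Union[Cell, str]] = {}
    for photo in photos:
        cell = _match_one(state, proj, photo, max_dist_m, max_dt_s)
        results[photo.filename] = cell if cell is not None else "UNMATCHED"
    return results


def _match_one(state, proj, photo, max_dist_m, max_dt_s):
    config = state.config
    if photo.location is not None and proj is not None:
        hit = geo_to_cell(proj, photo.location, config.rows, config.cols)
        if hit != OUTSIDE:
            return hit
        best = None
        for cell in config.cells():
            center = cell_center(proj, cell[0], cell[1], config.rows, config.cols)
            d = haversine(photo.location, center)
            if d <= max_dist_m and (best is None or (d, cell) < best):
                best = (d, cell)
        if best is not None:
            return best[1]
    if photo.timestamp is not None:
        ts = photo.timestamp
        best = None
        for cell in config.cells():
            for measurements in state.records[cell].measurements.values():
                for m in measurements:
                    dt = abs((m.timestamp - ts).total_seconds())
                    if dt <= max_dt_s and (best is None or (dt, cell) < best):
                        best = (dt, cell)
        if best is not None:
            return best[1]
    return None


def photo_meta_from_file(path) -> PhotoMeta:
    """Harvest PhotoMeta from an image file's EXIF header (thin adapter).

    Reads DateTimeOriginal and the GPS IFD via Pillow when available; fields
    that are absent stay ``None``. The matching operation itself consumes
    only :class:`PhotoMeta` records, so cameras without EXIF can still be
    matched by externally supplied metadata.
    """
    import os
    from datetime import timezone

    from PIL import ExifTags, Image

    timestamp = None
    location = None
    with Image.open(path) as img:
        exif = img.getexif()
        dto = exif.get_ifd(ExifTags.IFD.Exif).get(ExifTags.Base.DateTimeOriginal)
        if dto:
            timestamp = datetime.strptime(dto, "%Y:%m:%d %H:%M:%S").replace(
                tzinfo=timezone.utc
            )
        gps = exif.get_ifd(ExifTags.IFD.GPSInfo)
        if gps:
            lat = _dms_to_deg(gps.get(2), gps.get(1, "N"), "S")
            lon = _dms_to_deg(gps.get(4), gps.get(3, "E"), "W")
            if lat is not None and lon is not None:
                location = GeoPoint(lat=lat, lon=lon)
    return PhotoMeta(filename=os.path.basename(str(path)), timestamp=timestamp, location=location)


def _dms_to_deg(dms, ref, negative_ref):
    if not dms:
        return None
    deg = float(dms[0]) + float(dms[1]) / 60.0 + float(dms[2]) / 3600.0
    return -deg if ref == negative_ref else deg
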