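"""Serialization: configuration payloads, tab-delimited exports, image naming.

The configuration payload is the JSON document shared between devices
(typically rendered as a QR code): it uniquely identifies a trial setup, so
encoding is canonical — sorted keys, no insignificant whitespace — and two
equal configurations always produce byte-identical payloads.

Data exports are plain tab-delimited UTF-8 text with ``\\n`` line endings,
in the flat-file style that plant genetic resources databases such as
Germinate ingest: the wide layout has one row per plot with the latest
value per trait, the long layout one row per stored value with its
timestamp and recording GPS fix, and trait definitions export with their
ranges and categories so a trial can be rebuilt from its own files.
"""

from __future__ import annotations

import json
import re
from datetime import datetime, timezone
from typing import Iterable, Optional

from . import model
from .errors import ConfigurationError, PayloadError
from .geo import cell_center, fit_projection
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

_CONFIG_KEYS = {"name", "rows", "cols", "germplasm", "traits", "corners", "comment"}
_TRAIT_KEYS = {"name", "type", "min", "max", "categories", "multi"}
_ENTRY_KEYS = {"identifier", "rep", "barcode"}


# ---------------------------------------------------------------------------
# configuration payload (QR contract)

def encode_config(config: TrialConfig) -> str:
    """Canonical JSON payload for a trial configuration.

    Optional fields that are unset are omitted entirely, so identical
    configurations always yield byte-identical payloads.
    """
    doc: dict = {
        "name": config.name,
        "rows": config.rows,
        "cols": config.cols,
        "germplasm": [
            [_encode_entry(config.germplasm[(r, c)]) for c in range(config.cols)]
            for r in range(config.rows)
        ],
        "traits": [_encode_trait(t) for t in config.traits],
    }
    if config.corners is not None:
        doc["corners"] = [[p.lat, p.lon] for p in config.corners.corners]
    if config.comment is not None:
        doc["comment"] = config.comment
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def _encode_entry(entry: GermplasmEntry) -> dict:
    doc = {"identifier": entry.identifier}
    if entry.rep is not None:
        doc["rep"] = entry.rep
    if entry.barcode is not None:
        doc["barcode"] = entry.barcode
    return doc


def _encode_trait(trait: Trait) -> dict:
    doc: dict = {"name": trait.name, "type": trait.dtype.value, "multi": trait.multi}
    if trait.min is not None:
        doc["min"] = trait.min
    if trait.max is not None:
        doc["max"] = trait.max
    if trait.categories is not None:
        doc["categories"] = list(trait.categories)
    return doc


def decode_config(text: str) -> TrialConfig:
    """Parse and validate a configuration payload.

    Malformed JSON or unknown keys raise :class:`PayloadError`; structural
    invariant failures raise :class:`ConfigurationError` naming the field.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PayloadError(f"payload is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise PayloadError("payload must be a JSON object")
    _reject_unknown(doc, _CONFIG_KEYS, "payload")
    for key in ("name", "rows", "cols", "germplasm", "traits"):
        if key not in doc:
            raise ConfigurationError(f"payload missing required key {key!r}", field=key)
    rows, cols = doc["rows"], doc["cols"]
    if not isinstance(rows, int) or not isinstance(cols, int):
        raise ConfigurationError("rows and cols must be integers", field="rows")
    grid = doc["germplasm"]
    if not isinstance(grid, list) or any(not isinstance(row, list) for row in grid):
        raise ConfigurationError("germplasm must be a row-major list of lists", field="germplasm")
    if len(grid) != rows or any(len(row) != cols for row in grid):
        raise ConfigurationError(
            f"germplasm layout does not match the {rows}x{cols} grid", field="germplasm"
        )
    germplasm = {}
    for r, row in enumerate(grid):
        for c, cell in enumerate(row):
            _reject_unknown(cell, _ENTRY_KEYS, f"germplasm[{r}][{c}]")
            germplasm[(r, c)] = GermplasmEntry(
                identifier=cell.get("identifier", ""),
                rep=cell.get("rep"),
                barcode=cell.get("barcode"),
            )
    traits = []
    for i, tdoc in enumerate(doc["traits"]):
        _reject_unknown(tdoc, _TRAIT_KEYS, f"traits[{i}]")
        try:
            dtype = TraitType(tdoc.get("type"))
        except ValueError:
            raise ConfigurationError(
                f"traits[{i}]: unknown type {tdoc.get('type')!r}", field=f"traits[{i}].type"
            ) from None
        cats = tdoc.get("categories")
        traits.append(
            Trait(
                name=tdoc.get("name", ""),
                dtype=dtype,
                min=tdoc.get("min"),
                max=tdoc.get("max"),
                categories=tuple(cats) if cats is not None else None,
                multi=bool(tdoc.get("multi", False)),
            )
        )
    corners = None
    if "corners" in doc:
        pts = doc["corners"]
        if not isinstance(pts, list) or len(pts) != 4:
            raise ConfigurationError("corners must list exactly 4 [lat, lon] pairs", field="corners")
        corners = GeoQuad(tuple(GeoPoint(lat=p[0], lon=p[1]) for p in pts))
    return TrialConfig(
        name=doc["name"],
        rows=rows,
        cols=cols,
        germplasm=germplasm,
        traits=tuple(traits),
        corners=corners,
        comment=doc.get("comment"),
    )


def _reject_unknown(doc, allowed: set, where: str) -> None:
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{where} must be a JSON object", field=where)
    unknown = set(doc) - allowed
    if unknown:
        raise PayloadError(f"{where} has unknown key(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# tab-delimited exports

def _fmt_num(x) -> str:
    if isinstance(x, bool):  # pragma: no cover - bools never reach here
        raise TypeError
    if isinstance(x, int):
        return str(x)
    return repr(float(x))


def _centers(state: TrialState):
    config = state.config
    if config.corners is None:
        return {}
    proj = fit_projection(config.corners)
    return {
        (r, c): cell_center(proj, r, c, config.rows, config.cols)
        for r in range(config.rows)
        for c in range(config.cols)
    }


def export_wide(state: TrialState) -> str:
    """One row per plot (row-major), latest value and date per trait.

    Columns: Germplasm, Rep, Row, Column, Latitude, Longitude, then for each
    trait its value column and a ``<trait> Date`` column. Multi-measurement
    traits show the latest recording session's values joined by ``", "``.
    Plot coordinates come from the fitted corner projection when the trial
    has corners, otherwise the GPS columns are empty.
    """
    config = state.config
    centers = _centers(state)
    header = ["Germplasm", "Rep", "Row", "Column", "Latitude", "Longitude"]
    for t in config.traits:
        header += [t.name, f"{t.name} Date"]
    lines = ["\t".join(header)]
    for cell in config.cells():
        entry = config.germplasm[cell]
        center = centers.get(cell)
        row = [
            entry.identifier,
            entry.rep or "",
            str(cell[0]),
            str(cell[1]),
            repr(center.lat) if center else "",
            repr(center.lon) if center else "",
        ]
        record = state.records[cell]
        for t in config.traits:
            measurements = record.measurements.get(t.name, ())
            if measurements:
                latest = max(measurements, key=lambda m: m.timestamp)
                row.append(", ".join(serialize_value(t, v) for v in latest.values))
                row.append(latest.timestamp.date().isoformat())
            else:
                row += ["", ""]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


LONG_HEADER = (
    "Germplasm",
    "Rep",
    "Row",
    "Column",
    "Trait",
    "Value",
    "Timestamp",
    "Latitude",
    "Longitude",
)


def export_long(state: TrialState) -> str:
    """One row per stored value, with its timestamp and recording GPS fix.

    This is the lossless dialect: replaying it against the same
    configuration reconstructs an analytics-equivalent state (see
    :func:`replay_long`).
    """
    config = state.config
    lines = ["\t".join(LONG_HEADER)]
    for cell in config.cells():
        entry = config.germplasm[cell]
        record = state.records[cell]
        for t in config.traits:
            for m in record.measurements.get(t.name, ()):
                for v in m.values:
                    lines.append(
                        "\t".join(
                            [
                                entry.identifier,
                                entry.rep or "",
                                str(cell[0]),
                                str(cell[1]),
                                t.name,
                                serialize_value(t, v),
                                m.timestamp.astimezone(timezone.utc).isoformat(),
                                repr(m.location.lat) if m.location else "",
                                repr(m.location.lon) if m.location else "",
                            ]
                        )
                    )
    return "\n".join(lines) + "\n"


def replay_long(config: TrialConfig, text: str) -> TrialState:
    """Rebuild a trial state by replaying a long-format export.

    Consecutive rows sharing (plot, trait, timestamp, fix) are grouped back
    into one multi-value recording session before replay, so multi-value
    measurements survive the round trip.
    """
    lines = text.splitlines()
    if not lines or tuple(lines[0].split("\t")) != LONG_HEADER:
        raise PayloadError("not a long-format export: bad header")
    state = model.create_trial(config)
    pending_key = None
    pending: list[str] = []

    def flush():
        nonlocal state, pending
        if pending_key is not None:
            cell, trait_name, ts, loc = pending_key
            state = model.add_measurement(state, cell, trait_name, pending, ts, loc)
            pending = []

    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(LONG_HEADER):
            raise PayloadError(f"line {lineno}: expected {len(LONG_HEADER)} fields")
        _, _, r, c, trait_name, value, ts, lat, lon = fields
        cell = (int(r), int(c))
        timestamp = datetime.fromisoformat(ts)
        location = GeoPoint(lat=float(lat), lon=float(lon)) if lat and lon else None
        key = (cell, trait_name, timestamp, location)
        if key != pending_key:
            flush()
            pending_key = key
        pending.append(value)
    flush()
    return state


def export_traits(state_or_config) -> str:
    """Trait definitions with their ranges and categories, one row per trait."""
    config = getattr(state_or_config, "config", state_or_config)
    lines = ["\t".join(["Name", "Type", "Min", "Max", "Categories", "Multi"])]
    for t in config.traits:
        lines.append(
            "\t".join(
                [
                    t.name,
                    t.dtype.value,
                    _fmt_num(t.min) if t.min is not None else "",
                    _fmt_num(t.max) if t.max is not None else "",
                    "|".join(t.categories) if t.categories is not None else "",
                    "true" if t.multi else "false",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def parse_traits(text: str) -> tuple[Trait, ...]:
    """Re-import exported trait definitions."""
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != ["Name", "Type", "Min", "Max", "Categories", "Multi"]:
        raise PayloadError("not a trait-definition export: bad header")
    traits = []
    for line in lines[1:]:
        name, dtype, mn, mx, cats, multi = line.split("\t")
        traits.append(
            Trait(
                name=name,
                dtype=TraitType(dtype),
                min=_parse_num(mn),
                max=_parse_num(mx),
                categories=tuple(cats.split("|")) if cats else None,
                multi=multi == "true",
            )
        )
    return tuple(traits)


def _parse_num(text: str):
    if not text:
        return None
    return int(text) if re.fullmatch(r"-?\d+", text) else float(text)


# ---------------------------------------------------------------------------
# image tagging

_HOSTILE = re.compile(r'[/\\:*?"<>|\s]')


def image_filename(
    germplasm: str,
    timestamp: datetime,
    existing: Iterable[str] = (),
    extension: str = ".jpg",
) -> str:
    """Tagged filename ``<germplasm>_<YYYY-MM-DD-HH-mm-ss><ext>`` for a photo.

    Path-hostile characters and whitespace in the germplasm identifier are
    replaced with ``-``. If the name collides with one in ``existing``
    (same plot photographed twice in one second), a ``_2``, ``_3``, ...
    suffix disambiguates.
    """
    if not germplasm:
        raise ConfigurationError("germplasm identifier must be non-empty", field="germplasm")
    safe = _HOSTILE.sub("-", germplasm)
    stamp = timestamp.astimezone(timezone.utc).strftime("%Y-%m-%d-%H-%M-%S")
    base = f"{safe}_{stamp}"
    taken = set(existing)
    name = base + extension
    counter = 2
    while name in taken:
        name = f"{base}_{counter}{extension}"
        counter += 1
    return name


# ---------------------------------------------------------------------------
# full-state persistence (used by the command-line interface)

def encode_state(state: TrialState) -> str:
    """JSON document holding the configuration and every recorded datum."""
    records = {}
    for (r, c), record in state.records.items():
        if not (record.measurements or record.comments or record.bookmarked or record.images):
            continue
        doc: dict = {}
        if record.measurements:
            doc["measurements"] = {
                name: [
                    {
                        "values": [
                            serialize_value(state.config.trait(name), v) for v in m.values
                        ],
                        "timestamp": m.timestamp.isoformat(),
                        **(
                            {"location": [m.location.lat, m.location.lon]}
                            if m.location
                            else {}
                        ),
                    }
                    for m in measurements
                ]
                for name, measurements in record.measurements.items()
                if measurements
            }
        if record.comments:
            doc["comments"] = [
                {"text": cm.text, "timestamp": cm.timestamp.isoformat()}
                for cm in record.comments
            ]
        if record.bookmarked:
            doc["bookmarked"] = True
        if record.images:
            doc["images"] = list(record.images)
        records[f"{r},{c}"] = doc
    return json.dumps(
        {"config": json.loads(encode_config(state.config)), "records": records},
        sort_keys=True,
        separators=(",", ":"),
        ensure_ascii=False,
    )


def decode_state(text: str) -> TrialState:
    """Inverse of :func:`encode_state`; replays every datum through validation."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PayloadError(f"state file is not valid JSON: {exc}") from exc
    _reject_unknown(doc, {"config", "records"}, "state")
    config = decode_config(json.dumps(doc["config"]))
    state = model.create_trial(config)
    for key, rdoc in doc.get("records", {}).items():
        r, c = (int(x) for x in key.split(","))
        cell = (r, c)
        for name, mdocs in rdoc.get("measurements", {}).items():
            for m in mdocs:
                loc = m.get("location")
                state = model.add_measurement(
                    state,
                    cell,
                    name,
                    m["values"],
                    datetime.fromisoformat(m["timestamp"]),
                    GeoPoint(lat=loc[0], lon=loc[1]) if loc else None,
                )
        for cm in rdoc.get("comments", ()):
            state = model.add_comment(
                state, cell, cm["text"], datetime.fromisoformat(cm["timestamp"])
            )
        if rdoc.get("bookmarked"):
            state = model.toggle_bookmark(state, cell)
        for img in rdoc.get("images", ()):
            state = model.tag_image(state, cell, img)
    return state
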