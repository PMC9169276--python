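# Methods

This note records the models implemented by `fieldgrid`, the conventions
chosen where several were defensible, and what the synthetic fixtures do
and do not emulate.

## Trial model

A trial is a `rows × cols` grid; coordinates are 0-based `(row, col)` with
row 0 the top row of the field plan and column 0 the leftmost, matching the
top-down plan a scorer holds. Every cell carries exactly one germplasm
entry; barcodes, where assigned, must be unique so a scan identifies one
plot.

State operations are value-semantic: each returns a new `TrialState` and
never mutates its argument. This makes scoring histories trivially
testable and leaves room for undo in any front end.

Single-measurement traits **replace** on re-entry rather than refuse: in
the field the common case for re-scoring a plot is correcting a slip, and
the long export still shows only the surviving value. Multi-measurement
traits (season-long characters such as repeated yield picks) append one
recording session per entry; a session may carry several values.
Timestamps are normalized to UTC instants at the model boundary; local
display is a front-end concern, and exports stay unambiguous.

## Validation

Parsing is total: every raw string maps to exactly one of a typed value or
a `Violation` (`PARSE`, `RANGE` or `CATEGORY`), never an exception.
Conventions, fixed so exports are machine-stable:

- INT is strict (`-?\d+`): no decimal point, no `+`, no whitespace —
  a count trait should not silently accept `7.5`.
- FLOAT accepts ordinary and scientific decimal notation; NaN/inf are
  rejected because they cannot satisfy a range.
- DATE is ISO 8601 extended (`YYYY-MM-DD`), stored as the literal calendar
  date with no timezone arithmetic.
- Categorical matching is case-sensitive exact string membership:
  categories are pre-defined pick lists, not free input.
- Range bounds are inclusive at both ends; a missing bound is unbounded.

Floats serialize with Python's shortest round-tripping `repr`, so
parse → serialize → parse is a fixed point for every accepted value; the
test suite and the acceptance script verify this through a full
export/re-import cycle.

## Georeferencing

The four surveyed corners (ordered TL, TR, BR, BL of the field plan) define
a homography from the unit square in normalized grid coordinates — `u`
across columns, `v` down rows — to `(lon, lat)`. The 8 unknowns are solved
exactly from the four corner correspondences via the standard 8×8 linear
system with `H[2][2] = 1`; a singular system (degenerate corners) is a
geometry error, and three-collinear corner sets are already rejected when
the quad is constructed.

Longitude/latitude degrees are treated directly as planar coordinates.
Over the tens-to-hundreds of metres a field trial spans, the planar
approximation error is far below consumer GPS noise (metres); the
documented limitation is that fields spanning more than ~0.1° of latitude
or longitude should use a local metric projection instead.

Cells are half-open intervals `[i/n, (i+1)/n)` in each normalized axis so
every interior point resolves to exactly one plot; the far boundary
(`u` or `v` = 1 within 1e-9) is absorbed into the last cell, so the
bottom-right corner itself is resolvable. Fixes outside the quad return the
`OUTSIDE` sentinel rather than snapping.

Photo matching is a two-stage heuristic of this package's own design:
a photo with a GPS fix on a corner-surveyed trial takes the plot its fix
falls in, else the nearest plot center within `max_dist_m` (default 25 m —
generous against camera GPS error); failing that, the plot holding the
measurement closest in time within `max_dt_s` (default 300 s — one plot is
rarely scored for longer). Ties break to the lexicographically smaller
`(row, col)`. Unmatched photos are reported as values, not errors. EXIF
harvesting is a thin optional adapter; matching itself consumes plain
`PhotoMeta` records.

## Guided walks

The eight navigational sequences are interpreted as the natural family of
serpentine sweeps on a rectangle: {TL, TR, BL, BR start corner} × {row-major,
column-major}. This is the unique size-8 family of unit-step, every-plot-once
routes on a grid and matches field-scoring practice (no time walking back
along a lane). On degenerate 1×N grids some orders coincide; the mode list
still reports all eight modes. Starting mid-field fast-forwards to that
plot's position in the chosen sequence and ends at the route's end — it
does not re-anchor or wrap.

## Analytics

- A plot counts as *scored* for a trait when it holds ≥ 1 measurement.
- Timelines bucket by the UTC calendar date of each plot's **first**
  measurement of the trait; re-scores do not move the curve, because the
  chart measures coverage progress, not edits. All traits share the date
  axis (every date on which anything was recorded) so temporal
  relationships between traits are comparable.
- Quartiles use linear interpolation between order statistics (numpy
  default, R type 7) — the most common convention, fixed so exported
  summaries are reproducible. Date values are summarized as days since
  1970-01-01.
- Heat maps show each plot's most recent value (`latest`), the "current
  state" view of the field; `mean` over all values is available for
  multi-measurement numeric traits. Categories are encoded as their index
  in the pre-defined list. Free-text traits have no value scale and are
  rejected for summaries and heat maps.
- Scatter data is served as paired per-plot value vectors; drawing is out
  of scope.

## Serialization

The configuration payload (the QR-code content) is canonical JSON — sorted
keys, no insignificant whitespace, optional fields omitted — so equal
configurations are byte-identical and the payload can serve as a trial
fingerprint. Unknown keys are rejected rather than ignored, keeping the
contract closed. The exact column names of the wide export are this
package's fixed dialect (Germinate-style flat files do not mandate one):
`Germplasm, Rep, Row, Column, Latitude, Longitude`, then per trait a value
column (latest recording session; multiple values joined by `", "`) and a
`<trait> Date` column. The long export is the lossless dialect — one row
per stored value with ISO 8601 UTC timestamp and the recording fix — and
`replay_long` reconstructs an analytics-equivalent state from it, which the
suite verifies. Tagged image filenames are
`<germplasm>_<YYYY-MM-DD-HH-mm-ss>.jpg` with path-hostile characters
replaced by `-` and `_2`, `_3`, … suffixes on same-second collisions.

## Synthetic fixtures

`fixtures.SynthSpec` defaults describe a small cereal trial: 6×8 plots,
two float traits, one integer, one categorical and one date trait, scored
to 80 % coverage over a 5-day window. Timestamps fall uniformly within
08:00–18:00 UTC on a scoring day (a realistic field day); GPS fixes sit at
plot centers plus isotropic Gaussian jitter with a 2 m standard deviation,
the typical error of a phone GPS under open sky. A quarter of numeric
traits are generated as multi-measurement. The corner quad is an
axis-aligned rectangle at a fixed mid-latitude arable site sized at 1.5 m
plot pitch. All synthetic values go through the same validation path as
hand-entered text, and output is byte-deterministic for a fixed seed.

What the generator does **not** emulate: spatial autocorrelation of trait
values (so heat maps of synthetic data show noise, not gradients), genetic
or replicate effects, scorer-speed patterns along the walk, GPS multipath
or drift structure, and missing-not-at-random scoring gaps. Passing tests
therefore demonstrate the correctness of the mechanics (validation,
geometry, counting, serialization), not field realism of the data values.

## Problem sizes in the default suites

The bundled test and acceptance runs use grids up to 30×30 (all walks,
exhaustively), 1000 random corner quads with plot-center round trips on
grids up to 50×50, 100 synthetic scoring histories for the analytics
oracle comparison, and 1000 random configurations for payload round trips
— sizes chosen to exercise every boundary (1×1 and 1×N grids included)
while keeping the default suite fast on a single CPU.

## Known limitations

- Planar-degree projection (above); no altitude handling or GPS smoothing.
- No persistence beyond the CLI's JSON state file; no merge of concurrent
  edits from multiple devices.
- No unit handling or trait-ontology (e.g. Crop Ontology) linkage.
- The wide-export dialect is documented but not claimed bit-identical to
  any external database template.
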