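# fieldgrid

A headless Python toolkit for **manual field-trial phenotyping**: the
computational core behind grid-based scoring apps, usable as a library or
from the shell.

Plant breeding and crop research trials are laid out as a rows × columns
grid of plots, each planted with one germplasm entry (a line/accession,
possibly replicated). Scorers walk the field recording trait values —
plant height, heading date, growth habit — plot by plot. `fieldgrid`
models that workflow end to end:

- **Trial model** — immutable trial configuration (grid, germplasm layout,
  typed trait schema, optional surveyed corner points) plus value-semantic
  state operations: record measurements, comments, bookmarks, reset between
  scoring passes.
- **Validation** — type-driven parsing of raw text input (integer, float,
  categorical, date, free text) with inclusive range restrictions on numeric
  traits and pre-defined category pick lists, so bad values are rejected at
  entry with a precise violation (`PARSE` / `RANGE` / `CATEGORY`).
- **Georeferencing** — the four field corners define a planar projective
  transformation (homography) `H` mapping normalized grid coordinates
  `(u, v) ∈ [0,1]²` to `(lon, lat)`:
  `(lon, lat, 1)ᵀ ∝ H·(u, v, 1)ᵀ`, with the 8 parameters solved exactly
  from the corner correspondences. This resolves any GPS fix to its plot,
  places plot centers and outlines on a map, and matches photographs back
  to plots by GPS or timestamp.
- **Guided walks** — the eight serpentine (boustrophedon) traversals of a
  rectangular grid ({4 start corners} × {row-major, column-major}), with
  fast-forward from any starting plot.
- **Analytics** — per-trait scoring progress (overall, per row/column),
  cumulative coverage timelines, five-number trait summaries (type-7
  quantiles) and per-plot heat-map matrices.
- **Serialization** — canonical JSON configuration payloads (the content of
  a shared QR code), tab-delimited wide/long/trait-definition exports in
  Germinate-style flat-file form, lossless long-export replay, and tagged
  image filenames.
- **Fixtures** — a deterministic synthetic trial/scoring-season generator
  so everything is testable without field data.

## Worked example

```sh
$ fieldgrid synth --rows 2 --cols 3 --seed 4 -o config.json
wrote config.json
$ fieldgrid init config.json
initialized 2x3 trial 'Synthetic trial 4'
$ fieldgrid record 0 0 "Plant height" 120.5
recorded 'Plant height' at (0, 0)
$ fieldgrid record 0 1 "Growth habit" erect
recorded 'Growth habit' at (0, 1)
$ fieldgrid stats
# Plant height	1/6	0.167
min	120.5
...
# Growth habit	1/6	0.167
erect	1
intermediate	0
prostrate	0
...
$ fieldgrid walk tl-row | head -4
step	row	col	germplasm
1	0	0	G-0001
2	0	1	G-0002
3	0	2	G-0003
$ fieldgrid heatmap "Plant height"
120.5
```

`stats` prints, per trait, the scored/total plot count and fraction
(1 of 6 plots = 0.167) followed by the value distribution — a five-number
summary for numeric and date traits, category counts (including zero-count
categories) for categorical ones. `walk tl-row` is the serpentine route
starting at the top-left corner sweeping row by row; `heatmap` prints the
rows × columns grid of current values with empty cells for unscored plots.
Other subcommands: `barcode` (plot lookup by barcode), `locate lat lon`
(GPS fix → plot), `export --wide|--long|--traits`, `payload` (the canonical
QR JSON), `photos match`, `reset`.

The same operations are available as plain functions
(`fieldgrid.model`, `.validation`, `.geo`, `.navigation`, `.analytics`,
`.io`, `.fixtures`) on immutable state values.

## Scope

`fieldgrid` is deliberately headless: no UI, no chart rendering (analytics
return matrices and series), no persistence layer beyond the CLI's JSON
state file, no device synchronization, and no BrAPI endpoints.
See `docs/methods.md` for the models, conventions and their rationale.
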