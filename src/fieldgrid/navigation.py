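"""Guided-walk traversal orders through the field grid.

Field scorers walk a trial lane by lane, reversing direction at the end of
each lane (serpentine / boustrophedon order) so no time is lost returning
to the lane start. Eight navigational sequences exist for a rectangular
grid: the walk can begin at any of the four corners and sweep either
row-by-row or column-by-column. From any starting plot the guidance simply
fast-forwards to that plot's position in the chosen sequence and continues
to the end of the route.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConfigurationError, NotFoundError
from .model import Cell


class Corner(enum.Enum):
    TL = "top-left"
    TR = "top-right"
    BL = "bottom-left"
    BR = "bottom-right"


class Axis(enum.Enum):
    ROW = "row"
    COLUMN = "column"


@dataclass(frozen=True)
class WalkMode:
    """One of the eight guided-walk sequences: a start corner and a sweep axis."""

    start_corner: Corner
    major_axis: Axis


def list_modes() -> list[WalkMode]:
    """All eight walk modes, in a stable order (corners TL, TR, BL, BR; row before column)."""
    return [
        WalkMode(corner, axis)
        for corner in (Corner.TL, Corner.TR, Corner.BL, Corner.BR)
        for axis in (Axis.ROW, Axis.COLUMN)
    ]


def walk_order(rows: int, cols: int, mode: WalkMode) -> list[Cell]:
    """The serpentine visiting order of all cells for one walk mode.

    Starts at ``mode.start_corner``, sweeps lanes along ``mode.major_axis``,
    and reverses direction on each successive lane, so consecutive plots are
    always one step apart.
    """
    if rows < 1 or cols < 1:
        raise ConfigurationError(f"grid dimensions must be positive, got {rows}x{cols}")
    corner, axis = mode.start_corner, mode.major_axis
    top = corner in (Corner.TL, Corner.TR)
    left = corner in (Corner.TL, Corner.BL)

    order: list[Cell] = []
    if axis is Axis.ROW:
        lanes = range(rows) if top else range(rows - 1, -1, -1)
        forward = left
        for r in lanes:
            sweep = range(cols) if forward else range(cols - 1, -1, -1)
            order.extend((r, c) for c in sweep)
            forward = not forward
    else:
        lanes = range(cols) if left else range(cols - 1, -1, -1)
        forward = top
        for c in lanes:
            sweep = range(rows) if forward else range(rows - 1, -1, -1)
            order.extend((r, c) for r in sweep)
            forward = not forward
    return order


def walk_from(order: list[Cell], start: Cell) -> list[Cell]:
    """The remainder of a walk beginning at ``start`` (no wrap-around)."""
    try:
        i = order.index(start)
    except ValueError:
        raise NotFoundError(f"start cell {start} not on the walk") from None
    return order[i:]
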