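"""Rasterize field contours onto per-leaf-row bixel intervals.

A :class:`FieldGrid` holds, for every leaf row that overlaps the contour,
the open interval ``[x_start, x_end]`` snapped outward to the bixel
lattice. Bixel boundaries within a row are indexed 0-based from the row's
``x_start``; boundary ``j`` separates bixels ``j-1`` and ``j``. A global
lattice (integer multiples of ``bixel_width``) is shared by all rows so
that cross-row constraints can be expressed on common boundary positions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .contours import FieldContour
from .machine import MachineSpec


@dataclass(frozen=True)
class LeafRow:
    """One active leaf row of the rasterized field."""

    index: int          # leaf-pair index on the machine
    y_low: float        # cm, lower edge of the row
    y_high: float       # cm, upper edge
    x_start: float      # cm, lattice-aligned interval start
    x_end: float        # cm, lattice-aligned interval end

    @property
    def y_center(self) -> float:
        return 0.5 * (self.y_low + self.y_high)

    @property
    def width(self) -> float:
        return self.x_end - self.x_start


@dataclass(frozen=True)
class CarriageFlag:
    """Ordered same-bank leaf pair for which span constraints are needed."""

    n: int              # position in FieldGrid.rows
    m: int
    bank: str           # 'left' (trailing) or 'right' (leading)


class FieldGrid:
    """Per-leaf-row open intervals on a common bixel lattice."""

    def __init__(self, rows: list[LeafRow], bixel_width: float,
                 machine: MachineSpec, name: str = ""):
        if bixel_width <= 0:
            raise ValueError("bixel_width must be positive")
        self.rows = list(rows)
        self.bixel_width = float(bixel_width)
        self.machine = machine
        self.name = name
        for r in self.rows:
            if r.width < machine.min_gap - 1e-9:
                raise ValueError(
                    f"row {r.index}: interval width {r.width:.3f} cm below "
                    f"min_gap {machine.min_gap:.3f} cm")
            for x in (r.x_start, r.x_end):
                if abs(x / bixel_width - round(x / bixel_width)) > 1e-6:
                    raise ValueError(
                        f"row {r.index}: boundary {x} not on the bixel lattice")

    # --- lattice helpers -------------------------------------------------
    def n_bixels(self, i: int) -> int:
        r = self.rows[i]
        return int(round(r.width / self.bixel_width))

    def n_boundaries(self, i: int) -> int:
        return self.n_bixels(i) + 1

    def boundaries(self, i: int) -> np.ndarray:
        """Boundary x-positions (cm) of row i, 0-based from x_start."""
        r = self.rows[i]
        return r.x_start + self.bixel_width * np.arange(self.n_boundaries(i))

    def bixel_centers(self, i: int) -> np.ndarray:
        b = self.boundaries(i)
        return 0.5 * (b[:-1] + b[1:])

    def global_start_index(self, i: int) -> int:
        """Row i's x_start in global lattice units."""
        return int(round(self.rows[i].x_start / self.bixel_width))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def x_min(self) -> float:
        return min(r.x_start for r in self.rows)

    @property
    def x_max(self) -> float:
        return max(r.x_end for r in self.rows)

    @property
    def y_min(self) -> float:
        return min(r.y_low for r in self.rows)

    @property
    def y_max(self) -> float:
        return max(r.y_high for r in self.rows)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"FieldGrid({self.name or 'field'}: {self.n_rows} rows, "
                f"bixel {self.bixel_width} cm)")


def rasterize_contour(contour: FieldContour, machine: MachineSpec,
                      bixel_width: float = 0.2) -> FieldGrid:
    """Intersect each leaf-row centerline with the contour and snap outward.

    Rows whose centerline does not cross the contour are inactive. Rows
    narrower than the dynamic leaf gap are widened symmetrically (never
    narrowed) to ``min_gap``. Raises if a row's centerline crosses the
    contour in more than one interval (multiple apertures per row are out
    of scope) or if the rasterized field exceeds the overtravel or
    bank-span envelope.
    """
    if bixel_width <= 0:
        raise ValueError("bixel_width must be positive")
    g_ratio = machine.min_gap / bixel_width
    if abs(g_ratio - round(g_ratio)) > 1e-9:
        raise ValueError("min_gap must be an integer multiple of bixel_width")

    xmin, ymin, xmax, ymax = contour.bounds()
    w = machine.leaf_width
    # leaf rows are anchored so that row edges fall on multiples of leaf_width
    # with the central axis on a row boundary (80 pairs -> 40 per side)
    i_low = int(np.floor(ymin / w))
    i_high = int(np.ceil(ymax / w))
    half = machine.n_leaf_pairs // 2
    poly = contour.polygon
    span = max(abs(xmin), abs(xmax)) + 1.0

    rows: list[LeafRow] = []
    for i in range(i_low, i_high):
        if i < -half or i >= half:
            continue
        y_lo, y_hi = i * w, (i + 1) * w
        yc = 0.5 * (y_lo + y_hi)
        cut = poly.intersection(LineString([(-span, yc), (span, yc)]))
        if cut.is_empty:
            continue
        if cut.geom_type == "MultiLineString":
            raise ValueError(
                f"row at y={yc:.2f} cm intersects the contour in "
                f"{len(cut.geoms)} disjoint intervals; multiple apertures "
                "per row are not supported")
        if cut.geom_type != "LineString" or cut.length <= 0:
            continue  # grazing contact, no open interval
        x0, x1 = cut.bounds[0], cut.bounds[2]
        # snap outward to the lattice
        x0 = np.floor(x0 / bixel_width + 1e-9) * bixel_width
        x1 = np.ceil(x1 / bixel_width - 1e-9) * bixel_width
        if x1 - x0 < machine.min_gap - 1e-9:
            # widen symmetrically to min_gap, keeping lattice alignment
            need = int(round(machine.min_gap / bixel_width)) - int(round((x1 - x0) / bixel_width))
            left = need // 2
            right = need - left
            x0 -= left * bixel_width
            x1 += right * bixel_width
        rows.append(LeafRow(index=i + half, y_low=y_lo, y_high=y_hi,
                            x_start=round(x0, 9), x_end=round(x1, 9)))

    if not rows:
        raise ValueError("contour does not overlap any leaf row")

    _check_envelope(rows, machine)
    return FieldGrid(rows, bixel_width, machine, name=contour.name)


def leaf_travel_ranges(grid_or_rows, machine: MachineSpec):
    """Per-row leaf-tip travel ranges (cm), clamped by overtravel.

    The trailing (left-bank) tip sweeps ``[x_start, min(x_end - min_gap,
    +overtravel)]``; the leading (right-bank) tip sweeps
    ``[max(x_start + min_gap, -overtravel), x_end]``. The overtravel clamp
    implements the maximum-travel index bounds: beyond the clamp a leaf
    parks and the uncovered bixels stay exposed until beam-off (trailing)
    or from beam-on (leading).

    Returns four arrays: trail_start, trail_end, lead_start, lead_end.
    """
    rows = grid_or_rows.rows if isinstance(grid_or_rows, FieldGrid) else grid_or_rows
    g, ot = machine.min_gap, machine.overtravel
    bw = None
    if isinstance(grid_or_rows, FieldGrid):
        bw = grid_or_rows.bixel_width
    trail_start = np.array([r.x_start for r in rows])
    trail_end = np.array([min(r.x_end - g, ot) for r in rows])
    lead_start = np.array([max(r.x_start + g, -ot) for r in rows])
    lead_end = np.array([r.x_end for r in rows])
    if bw is not None:
        # keep clamped endpoints on the lattice (inward, never past the limit)
        trail_end = np.floor(trail_end / bw + 1e-9) * bw
        lead_start = np.ceil(lead_start / bw - 1e-9) * bw
    return trail_start, trail_end, lead_start, lead_end


def _check_envelope(rows: list[LeafRow], machine: MachineSpec) -> None:
    """Static reachability: overtravel past the centerline and bank span."""
    ts, te, ls, le = leaf_travel_ranges(rows, machine)
    ot, span = machine.overtravel, machine.bank_span
    for r, t0, l1 in zip(rows, ts, le):
        if t0 > ot + 1e-9:
            raise ValueError(
                f"row {r.index}: overtravel unachievable — the trailing leaf "
                f"must start {t0:.2f} cm past the centerline (limit {ot:.2f} cm)")
        if l1 < -ot - 1e-9:
            raise ValueError(
                f"row {r.index}: overtravel unachievable — the leading leaf "
                f"must end {-l1:.2f} cm past the centerline (limit {ot:.2f} cm)")
    for label, arr in (("trailing-bank start", ts), ("trailing-bank end", te),
                       ("leading-bank start", ls), ("leading-bank end", le)):
        if arr.max() - arr.min() > span + 1e-9:
            raise ValueError(
                f"bank span unachievable: {label} positions spread over "
                f"{arr.max() - arr.min():.2f} cm (carriage limit {span:.2f} cm)")


def detect_carriage_pairs(grid: FieldGrid, machine: MachineSpec | None = None
                          ) -> list[CarriageFlag]:
    """Exhaustive pairwise scan for potential same-bank span violations.

    For every ordered same-bank pair (n, m) the three preprocessing tests
    compare start-start, start-end and end-end tip positions; a pair is
    flagged when any difference exceeds the carriage span, and only flagged
    pairs receive span constraints in the optimization model.
    """
    machine = machine or grid.machine
    span = machine.bank_span
    flags: list[CarriageFlag] = []
    ts, te, ls, le = leaf_travel_ranges(grid, machine)
    for bank, (s, e) in (("left", (ts, te)), ("right", (ls, le))):
        for n in range(grid.n_rows):
            for m in range(grid.n_rows):
                if n == m:
                    continue
                if (abs(s[n] - s[m]) > span + 1e-9
                        or abs(s[n] - e[m]) > span + 1e-9
                        or abs(e[n] - e[m]) > span + 1e-9):
                    flags.append(CarriageFlag(n=n, m=m, bank=bank))
    return flags
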