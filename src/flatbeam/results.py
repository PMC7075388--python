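"""Trajectory solutions, derived fluence/time maps and constraint checks.

Times are seconds of beam-on time at the constant nominal dose rate of
the unflattened beam; fluence is ``x = DR * t`` in MU. For each leaf row
the four arrays ``r_in/r_out/l_in/l_out`` give the arrival/departure time
of the leading (right-bank) and trailing (left-bank) leaf at every bixel
boundary of the row, with parked conventions filled in: boundaries the
leading leaf starts beyond carry 0, boundaries the trailing leaf never
reaches carry the total beam-on time ``T``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import FieldGrid
from .machine import MachineSpec


@dataclass
class RowTrajectory:
    """Boundary crossing times of one leaf pair.

    ``x`` holds the boundary positions (cm, length J+1); the four time
    arrays have the same length. ``lead_start``/``trail_end`` are the
    boundary indices where the leading leaf parks at beam-on and the
    trailing leaf parks at beam-off (equal to the gap index G and J - G
    unless clamped by overtravel).
    """

    x: np.ndarray
    r_in: np.ndarray
    r_out: np.ndarray
    l_in: np.ndarray
    l_out: np.ndarray
    lead_start: int
    trail_end: int

    @property
    def n_boundaries(self) -> int:
        return len(self.x)

    def leading_curve(self, t_total: float) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear (time, tip position) curve of the leading leaf."""
        a = self.lead_start
        times = np.empty(2 * (len(self.x) - a))
        times[0::2] = self.r_in[a:]
        times[1::2] = self.r_out[a:]
        pos = np.repeat(self.x[a:], 2)
        return times, pos

    def trailing_curve(self, t_total: float) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear (time, tip position) curve of the trailing leaf."""
        e = self.trail_end
        times = np.empty(2 * (e + 1))
        times[0::2] = self.l_in[:e + 1]
        times[1::2] = self.l_out[:e + 1]
        pos = np.repeat(self.x[:e + 1], 2)
        return times, pos


@dataclass
class TrajectorySolution:
    """Optimal leaf trajectories for every active row plus total time."""

    rows: list[RowTrajectory]
    t_total: float
    grid: FieldGrid
    machine: MachineSpec

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def positions_at(self, t: float) -> np.ndarray:
        """(n_rows, 2) array of trailing/leading tip positions at time t."""
        out = np.empty((self.n_rows, 2))
        for i, row in enumerate(self.rows):
            tt, pp = row.trailing_curve(self.t_total)
            out[i, 0] = np.interp(t, tt, pp)
            tt, pp = row.leading_curve(self.t_total)
            out[i, 1] = np.interp(t, tt, pp)
        return out


@dataclass
class FluenceTimeMap:
    """Effective beam-on time per bixel and the equivalent fluence.

    ``t[i, j]`` is the exposure time (s) of global bixel column j in
    active row i; ``x = dose_rate_per_s * t`` is the fluence in MU.
    """

    t: np.ndarray
    grid: FieldGrid
    col0: int
    dose_rate_per_s: float

    @property
    def x(self) -> np.ndarray:
        return self.dose_rate_per_s * self.t

    @property
    def total_mu(self) -> float:
        return float(self.x.sum())


@dataclass
class TnGMap:
    """Tongue-and-groove strip times between adjacent rows (magnitudes).

    Entry ``[p, j]`` refers to the strip between adjacent-row pair p at
    global bixel column j. ``pairs`` lists the (row, row+1) index pairs.
    """

    t_ltg: np.ndarray
    t_rtg: np.ndarray
    pairs: list[tuple[int, int]]
    col0: int
    dose_rate_per_s: float

    @property
    def x_ltg(self) -> np.ndarray:
        return self.dose_rate_per_s * self.t_ltg

    @property
    def x_rtg(self) -> np.ndarray:
        return self.dose_rate_per_s * self.t_rtg

    @property
    def total(self) -> float:
        """Sum of T&G fluence magnitudes (MU), the Eq.-style penalty value."""
        return float(self.x_ltg.sum() + self.x_rtg.sum())


@dataclass
class ConstraintFamily:
    name: str
    worst_slack: float      # >= 0 means satisfied; units in `units`
    units: str
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.worst_slack >= -self.tolerance


@dataclass
class ConstraintReport:
    """Worst-case slack per constraint family of a delivered trajectory."""

    families: list[ConstraintFamily]

    @property
    def passed(self) -> bool:
        return all(f.passed for f in self.families)

    def __getitem__(self, name: str) -> ConstraintFamily:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)

    def summary(self) -> str:
        lines = [f"{'family':<22}{'worst slack':>14}  {'units':<6}{'pass'}"]
        for f in self.families:
            lines.append(f"{f.name:<22}{f.worst_slack:>14.3e}  "
                         f"{f.units:<6}{'yes' if f.passed else 'NO'}")
        return "\n".join(lines)


def _col_range(grid: FieldGrid, i: int, col0: int) -> tuple[int, int]:
    a = int(round(grid.rows[i].x_start / grid.bixel_width)) - col0
    return a, a + grid.n_bixels(i)


def effective_time(sol: TrajectorySolution) -> FluenceTimeMap:
    """Per-bixel effective beam-on time from the trapezoid of crossing times.

    ``t_nj = 0.5 * [(l_out[j] - r_out[j]) + (l_in[j+1] - r_in[j+1])]`` —
    exactly the time during which the bixel center is uncovered under
    linear leaf motion between boundaries.
    """
    grid = sol.grid
    bw = grid.bixel_width
    col0 = int(round(grid.x_min / bw))
    n_cols = int(round((grid.x_max - grid.x_min) / bw))
    t = np.zeros((sol.n_rows, n_cols))
    for i, row in enumerate(sol.rows):
        a, b = _col_range(grid, i, col0)
        tj = 0.5 * ((row.l_out[:-1] - row.r_out[:-1])
                    + (row.l_in[1:] - row.r_in[1:]))
        t[i, a:b] = tj
    return FluenceTimeMap(t=t, grid=grid, col0=col0,
                          dose_rate_per_s=sol.machine.dose_rate_mod_per_s)


def tng_times(sol: TrajectorySolution) -> TnGMap:
    """Tongue-and-groove strip times for each pair of adjacent leaves.

    The left-bank strip time compares the trailing-leaf crossing times of
    row n+1 against row n; the right-bank strip compares the leading-leaf
    times of row n against row n+1. Magnitudes are reported.
    """
    grid = sol.grid
    bw = grid.bixel_width
    col0 = int(round(grid.x_min / bw))
    n_cols = int(round((grid.x_max - grid.x_min) / bw))
    pairs = [(i, i + 1) for i in range(sol.n_rows - 1)
             if grid.rows[i + 1].index == grid.rows[i].index + 1]
    t_ltg = np.zeros((len(pairs), n_cols))
    t_rtg = np.zeros((len(pairs), n_cols))
    for p, (i, k) in enumerate(pairs):
        lo_i, li_i, ro_i, ri_i = _padded_times(sol, i, col0, n_cols)
        lo_k, li_k, ro_k, ri_k = _padded_times(sol, k, col0, n_cols)
        t_ltg[p] = 0.5 * np.abs((lo_k[:-1] + li_k[1:]) - (lo_i[:-1] + li_i[1:]))
        t_rtg[p] = 0.5 * np.abs((ro_i[:-1] + ri_i[1:]) - (ro_k[:-1] + ri_k[1:]))
    return TnGMap(t_ltg=t_ltg, t_rtg=t_rtg, pairs=pairs, col0=col0,
                  dose_rate_per_s=sol.machine.dose_rate_mod_per_s)


def _padded_times(sol: TrajectorySolution, i: int, col0: int, n_cols: int):
    """Row i crossing times extended over the global column lattice.

    Boundaries left of the row carry the trailing park time 0 / leading 0
    (both leaves start at or right of the row's left edge, so boundaries
    to the left were passed 'before' beam-on for the trailing leaf as
    well: the leaf bodies cover them throughout and the Eq.-style strip
    comparison needs times of the *tips*, which never visit them; the
    neutral convention is 0 on the left and T on the right for both).
    """
    row = sol.rows[i]
    a, _ = _col_range(sol.grid, i, col0)
    T = sol.t_total
    n_b = n_cols + 1

    def pad(arr):
        out = np.empty(n_b)
        out[:a] = 0.0
        out[a:a + len(arr)] = arr
        out[a + len(arr):] = T
        return out

    return pad(row.l_out), pad(row.l_in), pad(row.r_out), pad(row.r_in)


def validate_solution(sol: TrajectorySolution,
                      machine: MachineSpec | None = None,
                      grid: FieldGrid | None = None,
                      tol_time: float = 1e-5,
                      tol_space: float = 1e-4) -> ConstraintReport:
    """Re-check every machine constraint on the delivered trajectories.

    The gap and bank-span checks are evaluated on the reconstructed
    position-vs-time curves at the union of all trajectory breakpoints
    (between breakpoints every tip position is linear in time, so the
    worst case is attained at a breakpoint). Returns a report, never
    raises.
    """
    machine = machine or sol.machine
    grid = grid or sol.grid
    T = sol.t_total
    bw = grid.bixel_width
    dt_min = bw / machine.v_max

    order_slack = np.inf
    speed_slack = np.inf
    sync_slack = np.inf
    breakpoints = [np.array([0.0, T])]
    curves = []
    for row in sol.rows:
        a, e = row.lead_start, row.trail_end
        for tin, tout in ((row.r_in[a:], row.r_out[a:]),
                          (row.l_in[:e + 1], row.l_out[:e + 1])):
            order_slack = min(order_slack, float(np.min(tout - tin)))
            if len(tin) > 1:
                speed_slack = min(speed_slack,
                                  float(np.min(tin[1:] - tout[:-1]) - dt_min))
        sync_slack = min(sync_slack, -abs(float(row.l_out[e]) - T))
        tc = row.trailing_curve(T)
        lc = row.leading_curve(T)
        curves.append((tc, lc))
        breakpoints.extend([tc[0], lc[0]])

    times = np.unique(np.clip(np.concatenate(breakpoints), 0.0, T))
    trail_pos = np.empty((sol.n_rows, len(times)))
    lead_pos = np.empty((sol.n_rows, len(times)))
    for i, (tc, lc) in enumerate(curves):
        trail_pos[i] = np.interp(times, np.maximum.accumulate(tc[0]), tc[1])
        lead_pos[i] = np.interp(times, np.maximum.accumulate(lc[0]), lc[1])

    gap_slack = float((lead_pos - trail_pos).min() - machine.min_gap)
    over_slack = float(min(machine.overtravel - trail_pos.max(),
                           machine.overtravel + lead_pos.min()))
    span_slack = float(min(
        machine.bank_span - (trail_pos.max(axis=0) - trail_pos.min(axis=0)).max(),
        machine.bank_span - (lead_pos.max(axis=0) - lead_pos.min(axis=0)).max(),
    ))

    fams = [
        ConstraintFamily("ordering", order_slack, "s", tol_time),
        ConstraintFamily("speed", speed_slack, "s", tol_time),
        ConstraintFamily("min_gap", gap_slack, "cm", tol_space),
        ConstraintFamily("overtravel", over_slack, "cm", tol_space),
        ConstraintFamily("bank_span", span_slack, "cm", tol_space),
        ConstraintFamily("beam_off_sync", sync_slack, "s", tol_time),
    ]
    return ConstraintReport(families=fams)
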