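"""Control-point conversion, fluence reconstruction and plan export.

A machine delivers positions at monitor-unit checkpoints, not boundary
crossing times, so the optimized trajectories are sampled at equidistant
cumulative-MU (equivalently, time, at constant dose rate) control points
including both endpoints. The JSON plan format mirrors the RT-plan
control-point fields (cumulative meterset weight and per-bank leaf
positions); it is an inspection/export format, not clinical DICOM.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import FieldGrid
from .machine import MachineSpec
from .results import FluenceTimeMap, TrajectorySolution

PLAN_SCHEMA = {
    "type": "object",
    "required": ["format", "machine", "rows", "control_points"],
    "properties": {
        "format": {"type": "string", "const": "flatbeam-plan-1"},
        "machine": {
            "type": "object",
            "required": ["n_leaf_pairs", "leaf_width", "min_gap", "v_max",
                         "dose_rate_mod"],
        },
        "rows": {"type": "array", "items": {"type": "integer"}},
        "control_points": {
            "type": "array",
            "minItems": 2,
            "items": {
                "type": "object",
                "required": ["cumulative_mu", "left_cm", "right_cm"],
                "properties": {
                    "cumulative_mu": {"type": "number"},
                    "left_cm": {"type": "array", "items": {"type": "number"}},
                    "right_cm": {"type": "array", "items": {"type": "number"}},
                },
            },
        },
    },
}


@dataclass
class ControlPointSequence:
    """Ordered (cumulative MU, leaf positions) snapshots of one delivery.

    ``left``/``right`` are (n_points, n_rows) trailing/leading tip
    positions in cm; ``mu`` is strictly increasing from 0 to the total MU.
    ``row_indices`` are the machine leaf-pair indices of the rows.
    """

    mu: np.ndarray
    left: np.ndarray
    right: np.ndarray
    row_indices: list[int]
    machine: MachineSpec

    def __post_init__(self) -> None:
        if len(self.mu) < 2:
            raise ValueError("a control point sequence needs >= 2 points")
        if np.any(np.diff(self.mu) <= 0):
            raise ValueError("cumulative MU must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.mu)

    @property
    def mu_total(self) -> float:
        return float(self.mu[-1])

    def check(self, tol_space: float = 1e-4) -> None:
        """Raise if the sequence violates gap or speed limits."""
        gap = self.right - self.left
        if gap.min() < self.machine.min_gap - tol_space:
            raise ValueError(
                f"control points violate the minimum gap: {gap.min():.4f} cm")
        dt = np.diff(self.mu) / self.machine.dose_rate_mod_per_s
        for tips in (self.left, self.right):
            v = np.abs(np.diff(tips, axis=0)) / dt[:, None]
            if v.max() > self.machine.v_max * (1 + 1e-6) + tol_space:
                raise ValueError(
                    f"control points violate the leaf speed limit: "
                    f"{v.max():.3f} cm/s")


def sample_control_points(sol: TrajectorySolution, machine: MachineSpec | None = None,
                          n_points: int = 50) -> ControlPointSequence:
    """Sample trajectories at equidistant MU intervals (endpoints included).

    Each leaf's position at a sample time is the inverse of its
    piecewise-linear boundary crossing times; during a dwell interval the
    position is the boundary itself.
    """
    machine = machine or sol.machine
    if n_points < 2:
        raise ValueError("need at least two control points")
    T = sol.t_total
    times = np.linspace(0.0, T, n_points)
    mu = times * machine.dose_rate_mod_per_s
    left = np.empty((n_points, sol.n_rows))
    right = np.empty((n_points, sol.n_rows))
    for i, row in enumerate(sol.rows):
        for arr, (tt, pp) in ((left, row.trailing_curve(T)),
                              (right, row.leading_curve(T))):
            bad = np.diff(tt) < -1e-6
            if np.any(bad):
                j = int(np.argmax(bad))
                raise ValueError(
                    f"row {row.x[0]:.1f}..{row.x[-1]:.1f} cm: non-monotone "
                    f"crossing times at breakpoint {j}")
            arr[:, i] = np.interp(times, np.maximum.accumulate(tt), pp)
    return ControlPointSequence(
        mu=mu, left=left, right=right,
        row_indices=[r.index for r in sol.grid.rows], machine=machine)


def reconstruct_fluence(cps: ControlPointSequence,
                        grid: FieldGrid) -> FluenceTimeMap:
    """Effective beam-on time per bixel implied by the control points.

    Assumes linear leaf motion between control points and accumulates the
    time during which each bixel center is uncovered.
    """
    bw = grid.bixel_width
    col0 = int(round(grid.x_min / bw))
    n_cols = int(round((grid.x_max - grid.x_min) / bw))
    xc = (col0 + 0.5 + np.arange(n_cols)) * bw
    DR = cps.machine.dose_rate_mod_per_s
    times = cps.mu / DR
    t = np.zeros((len(grid.rows), n_cols))
    for i in range(len(grid.rows)):
        l, r = cps.left[:, i], cps.right[:, i]
        for k in range(len(times) - 1):
            dt = times[k + 1] - times[k]
            if dt <= 0:
                continue
            t[i] += _segment_exposure(xc, l[k], l[k + 1], r[k], r[k + 1], dt)
    return FluenceTimeMap(t=t, grid=grid, col0=col0, dose_rate_per_s=DR)


def _segment_exposure(xc, l0, l1, r0, r1, dt):
    """Time each center is inside (l(t), r(t)) for linear motion over dt."""
    sl = (l1 - l0) / dt
    sr = (r1 - r0) / dt
    # uncover time: when the leading tip passes xc (monotone non-decreasing)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_r = np.where(r0 >= xc, 0.0,
                         np.where(r1 <= xc, dt, (xc - r0) / max(sr, 1e-300)))
        tau_l = np.where(l1 <= xc, dt,
                         np.where(l0 >= xc, 0.0, (xc - l0) / max(sl, 1e-300)))
    return np.clip(np.minimum(tau_l, dt) - np.maximum(tau_r, 0.0), 0.0, dt)


def delivery_time(obj, machine: MachineSpec | None = None) -> float:
    """Total beam-on time in seconds of a solution or control-point sequence."""
    if isinstance(obj, TrajectorySolution):
        return 0.0 if not obj.rows else float(obj.t_total)
    if isinstance(obj, ControlPointSequence):
        return float(obj.mu_total / obj.machine.dose_rate_mod_per_s)
    raise TypeError("expected a TrajectorySolution or ControlPointSequence")


# ---------------------------------------------------------------------------
def plan_to_dict(cps: ControlPointSequence) -> dict:
    m = cps.machine
    return {
        "format": "flatbeam-plan-1",
        "machine": {
            "n_leaf_pairs": m.n_leaf_pairs, "leaf_width": m.leaf_width,
            "min_gap": m.min_gap, "v_max": m.v_max,
            "overtravel": m.overtravel, "bank_span": m.bank_span,
            "dose_rate_mod": m.dose_rate_mod, "dose_rate_ref": m.dose_rate_ref,
        },
        "rows": list(map(int, cps.row_indices)),
        "control_points": [
            {"cumulative_mu": float(cps.mu[k]),
             "left_cm": [float(v) for v in cps.left[k]],
             "right_cm": [float(v) for v in cps.right[k]]}
            for k in range(cps.n_points)
        ],
    }


def plan_from_dict(d: dict) -> ControlPointSequence:
    validate_plan(d)
    machine = MachineSpec(**d["machine"])
    mu = np.array([cp["cumulative_mu"] for cp in d["control_points"]])
    left = np.array([cp["left_cm"] for cp in d["control_points"]])
    right = np.array([cp["right_cm"] for cp in d["control_points"]])
    return ControlPointSequence(mu=mu, left=left, right=right,
                                row_indices=list(d["rows"]), machine=machine)


def validate_plan(d: dict) -> None:
    """Structural check of a plan dict against the shipped schema."""
    schema = PLAN_SCHEMA
    if not isinstance(d, dict):
        raise ValueError("plan must be a JSON object")
    for key in schema["required"]:
        if key not in d:
            raise ValueError(f"plan missing required key {key!r}")
    if d["format"] != "flatbeam-plan-1":
        raise ValueError(f"unknown plan format {d['format']!r}")
    for key in schema["properties"]["machine"]["required"]:
        if key not in d["machine"]:
            raise ValueError(f"plan machine header missing {key!r}")
    cps = d["control_points"]
    if len(cps) < 2:
        raise ValueError("plan needs >= 2 control points")
    n_rows = len(d["rows"])
    for k, cp in enumerate(cps):
        for key in ("cumulative_mu", "left_cm", "right_cm"):
            if key not in cp:
                raise ValueError(f"control point {k} missing {key!r}")
        if len(cp["left_cm"]) != n_rows or len(cp["right_cm"]) != n_rows:
            raise ValueError(f"control point {k} has wrong bank length")


def write_plan(cps: ControlPointSequence, path, format: str = "json") -> None:
    """Write the sequence as canonical JSON or a per-leaf CSV table.

    The sequence is re-validated against the gap/speed invariants on
    write. JSON round-trips bitwise through :func:`read_plan`; the CSV
    dialect rounds positions to 4 and MU to 3 decimals.
    """
    cps.check()
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(plan_to_dict(cps), indent=1))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            m = cps.machine
            w.writerow(["# flatbeam plan", f"dose_rate_mod={m.dose_rate_mod}",
                        f"min_gap={m.min_gap}", f"v_max={m.v_max}",
                        f"leaf_width={m.leaf_width}"])
            w.writerow(["control_point", "cumulative_mu", "leaf_pair",
                        "left_cm", "right_cm"])
            for k in range(cps.n_points):
                for i, idx in enumerate(cps.row_indices):
                    w.writerow([k, f"{cps.mu[k]:.3f}", idx,
                                f"{cps.left[k, i]:.4f}",
                                f"{cps.right[k, i]:.4f}"])
    else:
        raise ValueError(f"unknown plan format {format!r}")


def read_plan(path) -> ControlPointSequence:
    """Read a JSON plan written by :func:`write_plan`."""
    d = json.loads(Path(path).read_text())
    return plan_from_dict(d)
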