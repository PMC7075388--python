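"""Exhaustive lattice search over tiny trajectory problems.

An independent check of the convex optimizer: enumerate every monotone
trajectory whose crossing times lie on a regular time lattice, keep those
satisfying the ordering / speed / gap / beam-off constraints, and return
the best objective found. The convex optimum is a lower bound for the
lattice optimum; the gap between them is bounded by the lattice
resolution. Only feasible for one-row instances with a handful of
bixels; used for the golden regression fixtures and the oracle tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .machine import MachineSpec


@dataclass(frozen=True)
class TinyRowProblem:
    """One leaf row with an identity dose influence (dose = fluence).

    ``target`` is the desired fluence (MU) per bixel. The gap index is
    ``G = min_gap / bixel_width``; the leading leaf starts parked at
    boundary G, the trailing leaf at boundary 0, and the trailing leaf's
    final departure from boundary ``J - G`` defines the total time T.
    """

    n_bixels: int
    target: tuple
    machine: MachineSpec
    bixel_width: float = 0.2
    lambda1: float = 1.0
    lambda2: float = 1e-3

    def __post_init__(self) -> None:
        G = self.gap_index
        if self.n_bixels < G + 1:
            raise ValueError("row must be wider than the leaf gap")
        if len(self.target) != self.n_bixels:
            raise ValueError("target length must equal n_bixels")

    @property
    def gap_index(self) -> int:
        G = self.machine.min_gap / self.bixel_width
        if abs(G - round(G)) > 1e-9:
            raise ValueError("min_gap must be a multiple of bixel_width")
        return int(round(G))

    @property
    def dt_min(self) -> float:
        return self.bixel_width / self.machine.v_max

    def objective(self, times: dict) -> float:
        """Objective of a candidate trajectory given named crossing times."""
        J, G = self.n_bixels, self.gap_index
        T = times["T"]
        DR = self.machine.dose_rate_mod_per_s

        def at(name, j, lo, hi, low_val, high_val):
            if j < lo:
                return low_val
            if j > hi:
                return high_val
            return times[(name, j)]

        t = np.empty(J)
        for j in range(J):
            lo_ = at("l_out", j, 0, J - G - 1, 0.0, T)
            li = at("l_in", j + 1, 1, J - G, 0.0, T)
            ro = at("r_out", j, G, J - 1, 0.0, T)
            ri = at("r_in", j + 1, G + 1, J, 0.0, T)
            t[j] = 0.5 * ((lo_ - ro) + (li - ri))
        resid = DR * t - np.asarray(self.target, dtype=float)
        return self.lambda1 * float(resid @ resid) + self.lambda2 * T

    def feasible(self, times: dict) -> bool:
        J, G = self.n_bixels, self.gap_index
        T = times["T"]
        dt = self.dt_min
        eps = 1e-12
        for j in range(G, J):
            ro = times[("r_out", j)] if j <= J - 1 else T
            ri = times[("r_in", j)] if j >= G + 1 else 0.0
            if ri > ro + eps:
                return False
        for j in range(1, J - G + 1):
            lo_ = times[("l_out", j)] if j <= J - G - 1 else T
            li = times[("l_in", j)]
            if li > lo_ + eps:
                return False
        if times.get(("l_out", 0), T) < -eps:
            return False
        for j in range(G, J):        # leading speed
            ro = times[("r_out", j)]
            ri = times[("r_in", j + 1)] if j + 1 <= J else T
            if ri - ro < dt - eps:
                return False
        for j in range(0, J - G):    # trailing speed
            lo_ = times[("l_out", j)] if j <= J - G - 1 else T
            li = times[("l_in", j + 1)]
            if li - lo_ < dt - eps:
                return False
        for j in range(G, J):        # gap (departure family)
            lo_ = times[("l_out", j - G)] if j - G <= J - G - 1 else T
            if times[("r_out", j)] > lo_ + eps:
                return False
        for j in range(G + 1, J + 1):  # gap (arrival family)
            li = times[("l_in", j - G)] if j - G >= 1 else 0.0
            if times[("r_in", j)] > li + eps:
                return False
        if times[("r_in", J)] > T + eps:
            return False
        return True


def trajectory_names(problem: TinyRowProblem) -> list:
    """The free crossing times of the one-row problem, plus T."""
    J, G = problem.n_bixels, problem.gap_index
    return ([("r_out", j) for j in range(G, J)]
            + [("r_in", j) for j in range(G + 1, J + 1)]
            + [("l_out", j) for j in range(0, J - G)]
            + [("l_in", j) for j in range(1, J - G + 1)]
            + ["T"])


def exhaustive_lattice_search(problem: TinyRowProblem, t_max: float,
                              n_steps: int) -> tuple[float, dict]:
    """Best objective over all feasible lattice trajectories.

    All crossing times (including T) are restricted to the lattice
    ``linspace(0, t_max, n_steps + 1)``. Returns ``(objective, times)``.
    The enumeration is vectorized over the full product; keep the row at
    ``n_bixels <= gap_index + 2`` (5-7 free times).
    """
    J, G = problem.n_bixels, problem.gap_index
    lattice = np.linspace(0.0, t_max, n_steps + 1)
    names = trajectory_names(problem)
    grids = np.meshgrid(*([lattice] * len(names)), indexing="ij")
    col = {n: g.reshape(-1) for n, g in zip(names, grids)}
    del grids
    T = col["T"]
    dt = problem.dt_min
    eps = 1e-9

    def get(name, j, lo, hi, low_val, high_val):
        if j < lo:
            return low_val
        if j > hi:
            return high_val
        return col[(name, j)]

    mask = np.ones(T.shape, dtype=bool)

    def require_le(a, b, slack=0.0):
        nonlocal mask
        mask &= (a <= b - slack + eps)

    for j in range(G, J + 1):       # leading ordering r_in <= r_out
        require_le(get("r_in", j, G + 1, J, 0.0, T),
                   get("r_out", j, G, J - 1, 0.0, T))
    for j in range(1, J - G + 1):   # trailing ordering l_in <= l_out
        require_le(get("l_in", j, 1, J - G, 0.0, T),
                   get("l_out", j, 0, J - G - 1, 0.0, T))
    require_le(0.0, get("l_out", 0, 0, J - G - 1, 0.0, T))
    require_le(0.0, get("r_out", G, G, J - 1, 0.0, T))
    for j in range(G, J):           # leading speed
        require_le(get("r_out", j, G, J - 1, 0.0, T),
                   get("r_in", j + 1, G + 1, J, 0.0, T), slack=dt)
    for j in range(0, J - G):       # trailing speed
        require_le(get("l_out", j, 0, J - G - 1, 0.0, T),
                   get("l_in", j + 1, 1, J - G, 0.0, T), slack=dt)
    for j in range(G, J):           # gap, departure family
        require_le(get("r_out", j, G, J - 1, 0.0, T),
                   get("l_out", j - G, 0, J - G - 1, 0.0, T))
    for j in range(G + 1, J + 1):   # gap, arrival family
        require_le(get("r_in", j, G + 1, J, 0.0, T),
                   get("l_in", j - G, 1, J - G, 0.0, T))
    require_le(get("r_in", J, G + 1, J, 0.0, T), T)

    if not mask.any():
        raise RuntimeError("no feasible lattice trajectory found")
    idx = np.flatnonzero(mask)
    DR = problem.machine.dose_rate_mod_per_s
    obj = problem.lambda2 * T[idx]
    target = np.asarray(problem.target, dtype=float)
    for j in range(J):
        t_j = 0.5 * ((get("l_out", j, 0, J - G - 1, 0.0, T)
                      - get("r_out", j, G, J - 1, 0.0, T))
                     + (get("l_in", j + 1, 1, J - G, 0.0, T)
                        - get("r_in", j + 1, G + 1, J, 0.0, T)))
        t_j = t_j[idx] if isinstance(t_j, np.ndarray) else np.full(idx.shape, t_j)
        obj = obj + problem.lambda1 * (DR * t_j - target[j]) ** 2
    k = int(np.argmin(obj))
    sel = idx[k]
    times = {n: float(col[n][sel]) for n in names}
    return float(obj[k]), times
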