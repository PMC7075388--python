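"""Shared fixtures: machines, tiny grids, solved small fields."""
from __future__ import annotations

import numpy as np
import pytest

from flatbeam.contours import builtin_contour
from flatbeam.dose import DoseMap
from flatbeam.grid import FieldGrid, LeafRow, rasterize_contour
from flatbeam.machine import default_machine_spec
from flatbeam.model import LeafTrajectoryModel, Weights
from flatbeam.results import RowTrajectory, TrajectorySolution


@pytest.fixture(scope="session")
def machine():
    return default_machine_spec()


@pytest.fixture(scope="session")
def grid_10x10(machine):
    return rasterize_contour(builtin_contour("square", side=10.0), machine, 0.2)


def make_one_row_grid(machine, n_bixels=4, bixel=0.2, x_start=0.0, index=40):
    """A single-leaf-row field grid, n_bixels wide."""
    row = LeafRow(index=index, y_low=0.0, y_high=machine.leaf_width,
                  x_start=x_start, x_end=x_start + n_bixels * bixel)
    return FieldGrid([row], bixel, machine)


class IdentityInfluence:
    """Dose plane == bixel grid; dose == fluence. For oracle-level tests."""

    def __init__(self, grid):
        self.grid = grid
        bw = grid.bixel_width
        self.resolution = bw
        self.col0 = int(round(grid.x_min / bw))
        self.n_cols = int(round((grid.x_max - grid.x_min) / bw))
        self.n_rows = grid.n_rows
        self.mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        self.phi = np.ones((self.n_rows, self.n_cols))
        self.weights = [1.0]
        self.Yc = [np.eye(self.n_rows)]
        self.Xc = [np.eye(self.n_cols)]
        self.x = (self.col0 + 0.5 + np.arange(self.n_cols)) * bw
        self.y = np.array([r.y_center for r in grid.rows])

    @property
    def plane_shape(self):
        return (self.n_rows, self.n_cols)

    def dose(self, F):
        return DoseMap(np.asarray(F, dtype=float), self.resolution,
                       self.x[0], self.y[0])

    def adjoint(self, P):
        return np.asarray(P, dtype=float)

    def gram_apply(self, F):
        return np.asarray(F, dtype=float)


def identity_model(machine, n_bixels=4, target_mu=3.0, lambda2=1e-3,
                   x_start=0.0, prescription=35.0):
    """One-row trajectory model whose dose equals its fluence per bixel."""
    grid = make_one_row_grid(machine, n_bixels=n_bixels, x_start=x_start)
    infl = IdentityInfluence(grid)
    target = np.full((1, n_bixels), float(target_mu))
    ref = DoseMap(target / prescription, infl.resolution, infl.x[0], infl.y[0])
    return LeafTrajectoryModel(
        grid, infl, ref, weights=Weights(lambda1=1.0, lambda2=lambda2),
        machine=machine, prescription_mu=prescription)


def lagged_sweep_rows(grid, machine, rate=0.5, lag=2.0, row_lags=None):
    """Hand-built constant-velocity double-sweep trajectories.

    Every leaf moves at constant ``rate`` seconds per bixel with no
    dwells except parking; the trailing leaf lags the leading one by
    ``lag`` seconds. ``row_lags`` optionally shifts whole rows in time
    (the last row pins the shared beam-off time, so only earlier rows
    may be shifted negatively).
    """
    G = int(round(machine.min_gap / grid.bixel_width))
    row_lags = row_lags or [0.0] * grid.n_rows
    if min(row_lags) < 0:
        raise ValueError("row lags must be non-negative (dwell at start)")
    t_end = max(row_lags[i] + lag + rate * (grid.n_bixels(i) - G)
                for i in range(grid.n_rows))
    rows = []
    for i in range(grid.n_rows):
        J = grid.n_bixels(i)
        a, e = G, J - G
        off = row_lags[i]
        r_in = np.zeros(J + 1)
        r_out = np.zeros(J + 1)
        l_in = np.zeros(J + 1)
        l_out = np.zeros(J + 1)
        for j in range(J + 1):
            cross_r = off + rate * (j - a)
            r_in[j] = 0.0 if j <= a else cross_r
            r_out[j] = cross_r if a <= j < J else (0.0 if j < a else t_end)
            cross_l = off + lag + rate * j
            l_in[j] = 0.0 if j == 0 else min(cross_l, t_end)
            l_out[j] = cross_l if j < e else t_end
        rows.append(RowTrajectory(x=grid.boundaries(i), r_in=r_in,
                                  r_out=r_out, l_in=l_in, l_out=l_out,
                                  lead_start=a, trail_end=e))
    return TrajectorySolution(rows=rows, t_total=float(t_end), grid=grid,
                              machine=machine)


@pytest.fixture(scope="session")
def solved_6x6(machine):
    """A solved small square field (shared across tests)."""
    model = LeafTrajectoryModel.from_field("square", side=6.0, machine=machine)
    return model, model.fit()
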