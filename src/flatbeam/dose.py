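"""Dose influence and dose maps on the 2D evaluation plane.

The evaluation plane is the conventional 10 cm depth / 100 cm SAD plane,
used purely as a 2D geometry — no depth physics is modeled. The influence
of bixel (n, j) on voxel i is the off-axis intensity at the bixel center
times the scatter kernel integrated over the bixel footprint and sampled
at the voxel center. Because the kernel is a weighted sum of isotropic
Gaussians this factorizes exactly into small 1D operators per kernel
component (a Kronecker structure), which is how :class:`DoseInfluence`
stores and applies it; :meth:`DoseInfluence.tosparse` materializes the
equivalent sparse matrix (weights below 1e-6 of the peak dropped) for
small problems and cross-checks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import erf

from .beam import BeamModel
from .grid import FieldGrid

log = logging.getLogger(__name__)

SPARSE_DROP = 1e-6  # relative weight threshold for materialized matrices


@dataclass
class DoseMap:
    """Dose values sampled at voxel centers of the evaluation plane.

    ``values[iy, ix]`` is the dose at ``(x0 + ix*resolution,
    y0 + iy*resolution)`` in arbitrary units (MU-equivalent fluence units
    straight from the influence operator unless normalized).
    """

    values: np.ndarray
    resolution: float
    x0: float
    y0: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("dose map must be 2D")
        if not np.all(np.isfinite(v)):
            raise ValueError("dose map contains non-finite values")
        if np.any(v < -1e-9 * max(1.0, np.abs(v).max())):
            raise ValueError("dose map contains negative values")
        self.values = np.clip(v, 0.0, None)

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.resolution * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.resolution * np.arange(self.values.shape[0])

    def cax_value(self) -> float:
        """Dose at the beam central axis (0, 0)."""
        return float(self.at(0.0, 0.0))

    def at(self, x: float, y: float) -> float:
        """Bilinear interpolation at a point (cm)."""
        fx = (x - self.x0) / self.resolution
        fy = (y - self.y0) / self.resolution
        ny, nx = self.values.shape
        if not (0 <= fx <= nx - 1 and 0 <= fy <= ny - 1):
            raise ValueError(f"point ({x}, {y}) outside the dose plane")
        ix, iy = int(np.floor(fx)), int(np.floor(fy))
        ix = min(ix, nx - 2)
        iy = min(iy, ny - 2)
        tx, ty = fx - ix, fy - iy
        v = self.values
        return float((1 - ty) * ((1 - tx) * v[iy, ix] + tx * v[iy, ix + 1])
                     + ty * ((1 - tx) * v[iy + 1, ix] + tx * v[iy + 1, ix + 1]))

    def normalized(self, value: float | None = None) -> "DoseMap":
        """Scale so the CAX (or the given value) maps to 1.0."""
        ref = self.cax_value() if value is None else value
        if ref <= 0:
            raise ValueError("cannot normalize to a non-positive value")
        return DoseMap(self.values / ref, self.resolution, self.x0, self.y0)

    def to_csv(self, path) -> None:
        header = (f"flatbeam dose map\nresolution_cm,{self.resolution}\n"
                  f"x0_cm,{self.x0}\ny0_cm,{self.y0}\n")
        with open(path, "w") as fh:
            fh.write("".join("# " + line + "\n" for line in header.splitlines()))
            np.savetxt(fh, self.values, delimiter=",", fmt="%.8g")


def _gauss_edge(z: np.ndarray) -> np.ndarray:
    """Cumulative unit Gaussian: response of an edge at distance z sigmas."""
    return 0.5 * (1.0 + erf(z / np.sqrt(2.0)))


class DoseInfluence:
    """Factorized influence of per-bixel fluence on plane voxels.

    Fluence is a dense array ``F[n, j]`` over the grid's active rows and
    the global bixel columns spanning all rows; columns outside a row's
    interval carry no fluence (leaf bodies shield them). For each kernel
    component ``c`` with weight ``w_c``::

        dose = sum_c w_c * Y_c @ (phi * F) @ X_c.T

    where ``phi`` is the off-axis factor at bixel centers, ``Y_c`` spreads
    a row's 0.5 cm footprint onto voxel rows and ``X_c`` a bixel's width
    onto voxel columns (both exact Gaussian edge-response differences).
    """

    def __init__(self, grid: FieldGrid, beam: BeamModel,
                 resolution: float = 0.2, margin: float = 3.0):
        if margin < 2.0:
            raise ValueError("dose plane must extend >= 2 cm beyond the field")
        ratio = max(grid.bixel_width / resolution, resolution / grid.bixel_width)
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "plane resolution and bixel width must be related by an "
                f"integer ratio (bixel {grid.bixel_width} cm vs {resolution} cm)")
        self.grid = grid
        self.beam = beam
        self.resolution = float(resolution)

        bw = grid.bixel_width
        # global bixel columns covering every row interval
        self.col0 = int(round(grid.x_min / bw))
        self.n_cols = int(round((grid.x_max - grid.x_min) / bw))
        self.n_rows = grid.n_rows

        nx = int(np.ceil((max(abs(grid.x_min), grid.x_max) + margin) / resolution))
        ny = int(np.ceil((max(abs(grid.y_min), grid.y_max) + margin) / resolution))
        self.x = resolution * np.arange(-nx, nx + 1)
        self.y = resolution * np.arange(-ny, ny + 1)

        # bixel-center coordinates and off-axis factor with aperture mask
        xc = (self.col0 + 0.5 + np.arange(self.n_cols)) * bw
        yc = np.array([r.y_center for r in grid.rows])
        self.mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for i, r in enumerate(grid.rows):
            a = int(round(r.x_start / bw)) - self.col0
            b = int(round(r.x_end / bw)) - self.col0
            self.mask[i, a:b] = True
        self.phi = beam.intensity_xy(xc[None, :], yc[:, None]) * self.mask

        # 1D factor operators per kernel component
        self.weights = [w for _, w in beam.kernel]
        self.Xc, self.Yc = [], []
        for s, _ in beam.kernel:
            xl = (self.col0 + np.arange(self.n_cols)) * bw
            self.Xc.append(_gauss_edge((self.x[:, None] - xl[None, :]) / s)
                           - _gauss_edge((self.x[:, None] - (xl + bw)[None, :]) / s))
            ylo = np.array([r.y_low for r in grid.rows])
            yhi = np.array([r.y_high for r in grid.rows])
            self.Yc.append(_gauss_edge((self.y[:, None] - ylo[None, :]) / s)
                           - _gauss_edge((self.y[:, None] - yhi[None, :]) / s))
        self._gram = None

    # --- forward / adjoint -----------------------------------------------
    def dose(self, fluence: np.ndarray) -> DoseMap:
        """Apply the influence to a fluence array (n_rows, n_cols)."""
        F = self._check(fluence) * self.phi
        vals = np.zeros((len(self.y), len(self.x)))
        for w, Y, X in zip(self.weights, self.Yc, self.Xc):
            vals += w * (Y @ F @ X.T)
        return DoseMap(vals, self.resolution, self.x[0], self.y[0])

    def _check(self, fluence: np.ndarray) -> np.ndarray:
        F = np.asarray(fluence, dtype=float)
        if F.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"fluence shape {F.shape} != {(self.n_rows, self.n_cols)}")
        return F

    def adjoint(self, plane: np.ndarray) -> np.ndarray:
        """Adjoint map: plane array -> fluence-grid array."""
        out = np.zeros((self.n_rows, self.n_cols))
        for w, Y, X in zip(self.weights, self.Yc, self.Xc):
            out += w * (Y.T @ plane @ X)
        return out * self.phi

    def gram_apply(self, fluence: np.ndarray) -> np.ndarray:
        """Apply ``D^T D`` to a fluence array via precomputed small Grams."""
        if self._gram is None:
            gy, gx = [], []
            for a in range(len(self.weights)):
                for b in range(len(self.weights)):
                    w = self.weights[a] * self.weights[b]
                    gy.append(w * (self.Yc[a].T @ self.Yc[b]))
                    gx.append(self.Xc[a].T @ self.Xc[b])
            self._gram = (gy, gx)
        gy, gx = self._gram
        F = self._check(fluence) * self.phi
        out = np.zeros_like(F)
        for Gy, Gx in zip(gy, gx):
            out += Gy @ F @ Gx.T
        return out * self.phi

    @property
    def plane_shape(self) -> tuple[int, int]:
        return (len(self.y), len(self.x))

    @property
    def n_voxels(self) -> int:
        return len(self.y) * len(self.x)

    # --- materialization ---------------------------------------------------
    def tosparse(self) -> sparse.csr_matrix:
        """Equivalent sparse matrix (n_voxels, n_rows*n_cols).

        Voxel index ``iy*nx + ix``, bixel index ``n*n_cols + j``. Entries
        below 1e-6 of the matrix peak are dropped.
        """
        D = None
        for w, Y, X in zip(self.weights, self.Yc, self.Xc):
            term = w * sparse.kron(sparse.csr_matrix(Y), sparse.csr_matrix(X))
            D = term if D is None else D + term
        D = D @ sparse.diags(self.phi.ravel())
        D = D.tocsr()
        peak = np.abs(D.data).max() if D.nnz else 0.0
        if peak > 0:
            D.data[np.abs(D.data) < SPARSE_DROP * peak] = 0.0
            D.eliminate_zeros()
        return D


def build_dose_influence(grid: FieldGrid, beam: BeamModel,
                         resolution: float = 0.2,
                         margin: float = 3.0) -> DoseInfluence:
    """Construct the dose influence for a rasterized field and beam."""
    return DoseInfluence(grid, beam, resolution=resolution, margin=margin)


def compute_dose(fluence: np.ndarray, influence: DoseInfluence) -> DoseMap:
    """Dose map from a fluence array: d_i = sum_nj D_nij x_nj."""
    return influence.dose(fluence)


def reference_flat_dose(grid: FieldGrid, beam_flat: BeamModel,
                        resolution: float = 0.1,
                        margin: float = 3.0) -> DoseMap:
    """Desired planar dose: unit fluence over the aperture, flat beam.

    Flat in-field with a smooth kernel penumbra, normalized to 1.0 at the
    central axis (or at the aperture centroid, with a warning, if the axis
    lies outside the aperture).
    """
    if beam_flat.mode != "flat":
        raise ValueError("reference dose requires a flat-mode beam")
    infl = DoseInfluence(grid, beam_flat, resolution=resolution, margin=margin)
    dm = infl.dose(np.ones((infl.n_rows, infl.n_cols)) * infl.mask)
    if _cax_in_aperture(grid):
        return dm.normalized()
    cx, cy = _aperture_centroid(grid)
    log.warning("central axis outside the aperture; normalizing the "
                "reference dose at the aperture centroid (%.2f, %.2f) cm",
                cx, cy)
    return dm.normalized(dm.at(cx, cy))


def _cax_in_aperture(grid: FieldGrid) -> bool:
    for r in grid.rows:
        if r.y_low <= 0.0 <= r.y_high and r.x_start <= 0.0 <= r.x_end:
            return True
    return False


def _aperture_centroid(grid: FieldGrid) -> tuple[float, float]:
    areas = np.array([r.width * (r.y_high - r.y_low) for r in grid.rows])
    cxs = np.array([(r.x_start + r.x_end) / 2.0 for r in grid.rows])
    cys = np.array([r.y_center for r in grid.rows])
    return (float(np.average(cxs, weights=areas)),
            float(np.average(cys, weights=areas)))
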