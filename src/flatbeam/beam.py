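"""Synthetic beam model: off-axis intensity and scatter/penumbra kernel.

The unflattened (FFF) mode uses a radial polynomial stand-in for the
forward-peaked intensity of a 6 MV filter-free beam, calibrated to the
typical published falloff (≈0.70 of the axis value at 10 cm off axis,
≈0.45 at 20 cm) and clipped below at 0.2. The flat mode is identically
1.0 and generates the flat reference. The kernel is a sum of two
isotropic Gaussians — a narrow penumbra core and a wide low-weight
scatter tail — and integrates to 1 over the plane.

None of this is commissioned data; users can substitute a measured
off-axis table (two-column text: radius_cm, relative_intensity).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# radial polynomial 1 - a r + b r^2 fitted to (10 cm, 0.70), (20 cm, 0.45)
_FFF_A = 0.0325
_FFF_B = 0.00025
_FFF_FLOOR = 0.2

#: default double-Gaussian kernel: (sigma_cm, weight)
DEFAULT_KERNEL = ((0.25, 0.85), (1.5, 0.15))


def fff_off_axis(r, a: float = _FFF_A, b: float = _FFF_B,
                 floor: float = _FFF_FLOOR):
    """Forward-peaked relative intensity at radius ``r`` (cm) from the axis.

    1.0 on the axis, smoothly decreasing (1 - a*r + b*r^2), clipped below
    at ``floor``. Raises for negative radii.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("off-axis radius must be non-negative")
    out = 1.0 - a * r + b * r * r
    out = np.clip(out, floor, 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BeamModel:
    """Off-axis intensity (``fff`` or ``flat`` mode) plus scatter kernel.

    ``kernel`` is a tuple of (sigma_cm, weight) Gaussian components whose
    weights sum to 1. ``oar_table`` optionally overrides the parametric
    off-axis curve with a measured (radius, intensity) table, linearly
    interpolated.
    """

    mode: str = "fff"
    kernel: tuple = DEFAULT_KERNEL
    grid_resolution: float = 0.1
    oar_table: tuple | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fff", "flat"):
            raise ValueError("mode must be 'fff' or 'flat'")
        w = sum(w for _, w in self.kernel)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")
        if any(s <= 0 or w < 0 for s, w in self.kernel):
            raise ValueError("kernel sigmas must be positive, weights >= 0")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")

    def off_axis(self, r):
        """Relative intensity at radius r (cm)."""
        if self.mode == "flat":
            r = np.asarray(r, dtype=float)
            if np.any(r < 0):
                raise ValueError("off-axis radius must be non-negative")
            out = np.ones_like(r)
            return out if out.ndim else 1.0
        if self.oar_table is not None:
            radii, vals = self.oar_table
            r = np.asarray(r, dtype=float)
            if np.any(r < 0):
                raise ValueError("off-axis radius must be non-negative")
            out = np.interp(r, radii, vals)
            return out if out.ndim else float(out)
        return fff_off_axis(r)

    def intensity_xy(self, x, y):
        """Off-axis factor on a cartesian grid (broadcasts x against y)."""
        return self.off_axis(np.hypot(x, y))

    def kernel_1d(self, spacing: float, component: int) -> np.ndarray:
        """Discretized 1D Gaussian factor of one kernel component.

        Cell-integrated (erf differences) on a symmetric lattice with the
        given spacing, truncated where the 1D profile falls below 1e-8 of
        its peak; normalized so the component's 2D kernel sums to 1 before
        weighting.
        """
        from scipy.special import erf
        sigma, _ = self.kernel[component]
        half = int(np.ceil(sigma * 6.5 / spacing))
        edges = (np.arange(-half, half + 1 + 1) - 0.5) * spacing
        z = edges / (sigma * np.sqrt(2.0))
        col = 0.5 * (erf(z[1:]) - erf(z[:-1]))
        col /= col.sum()
        return col

    def kernel_2d(self, spacing: float) -> np.ndarray:
        """Full discretized kernel (sums to 1) on a square lattice."""
        parts = []
        size = 0
        for c, (_, w) in enumerate(self.kernel):
            k1 = self.kernel_1d(spacing, c)
            parts.append((w, k1))
            size = max(size, len(k1))
        out = np.zeros((size, size))
        for w, k1 in parts:
            pad = (size - len(k1)) // 2
            k2 = np.outer(k1, k1)
            out[pad:pad + len(k1), pad:pad + len(k1)] += w * k2
        return out

    def penumbra_sigma(self) -> float:
        """Effective RMS width of the kernel (cm), for reporting."""
        return float(np.sqrt(sum(w * s * s for s, w in self.kernel)))


def flat_reference_beam(kernel: tuple = DEFAULT_KERNEL,
                        grid_resolution: float = 0.1) -> BeamModel:
    """Flat-mode beam with the same kernel (the flattened reference)."""
    return BeamModel(mode="flat", kernel=kernel, grid_resolution=grid_resolution)


def read_off_axis_table(path) -> tuple:
    """Load a two-column (radius_cm, relative_intensity) text table."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        rows.append((float(parts[0]), float(parts[1])))
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    return (arr[order, 0], arr[order, 1])
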