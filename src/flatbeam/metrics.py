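"""Dose-map evaluation: profiles, IEC-style flatness, gamma, T&G dips.

Flatness follows the IEC 60976 form 100*(Dmax-Dmin)/(Dmax+Dmin) over the
flattened region, taken here (configurably) as the central 80% of the
stated field width. Gamma uses the Low formalism with *local* dose
normalization, a dose threshold relative to the central-axis reference
dose, a search radius of 3x the distance-to-agreement and the reference
interpolated to steps of at most DTA/10. Gamma is asymmetric in
(evaluated, reference); the reference argument is the flat target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .dose import DoseMap


@dataclass
class Profile:
    """1D normalized dose profile along crossline (x) or inline (y)."""

    positions: np.ndarray
    values: np.ndarray
    axis: str = "crossline"
    offset: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if p.ndim != 1 or p.shape != v.shape:
            raise ValueError("positions and values must be matching 1D arrays")
        if np.any(np.diff(p) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("profile values must be non-negative")
        self.positions, self.values = p, v


@dataclass
class GammaResult:
    """Per-voxel gamma values and the pass statistics."""

    gamma: np.ndarray           # NaN where below the dose threshold
    pass_fraction: float        # percent of included voxels with gamma <= 1
    n_included: int
    criteria: dict

    @property
    def passed(self) -> np.ndarray:
        return self.gamma <= 1.0


def extract_profile(d: DoseMap, axis: str = "crossline",
                    offset: float = 0.0) -> Profile:
    """Cut through the dose map, normalized to the central-axis value.

    ``crossline`` runs along x at y=offset; ``inline`` along y at
    x=offset.
    """
    cax = d.cax_value()
    if cax <= 0:
        raise ValueError("cannot normalize: zero dose at the central axis")
    if axis == "crossline":
        if not d.y[0] <= offset <= d.y[-1]:
            raise ValueError(f"offset {offset} cm outside the map")
        frac = (offset - d.y0) / d.resolution
        i0 = min(int(np.floor(frac)), d.values.shape[0] - 2)
        w = frac - i0
        vals = (1 - w) * d.values[i0] + w * d.values[i0 + 1]
        return Profile(d.x.copy(), vals / cax, axis=axis, offset=offset)
    if axis == "inline":
        if not d.x[0] <= offset <= d.x[-1]:
            raise ValueError(f"offset {offset} cm outside the map")
        frac = (offset - d.x0) / d.resolution
        i0 = min(int(np.floor(frac)), d.values.shape[1] - 2)
        w = frac - i0
        vals = (1 - w) * d.values[:, i0] + w * d.values[:, i0 + 1]
        return Profile(d.y.copy(), vals / cax, axis=axis, offset=offset)
    raise ValueError("axis must be 'crossline' or 'inline'")


def iec_flatness(p: Profile, field_bounds: tuple[float, float],
                 flattened_fraction: float = 0.8) -> float:
    """Flatness 100*(Dmax-Dmin)/(Dmax+Dmin) over the flattened region.

    The flattened region is the central ``flattened_fraction`` of the
    stated field width, centered in the field.
    """
    lo, hi = field_bounds
    if hi <= lo:
        raise ValueError("field bounds must satisfy lo < hi")
    if p.positions[0] > lo or p.positions[-1] < hi:
        raise ValueError("profile does not span the field bounds")
    c, hw = 0.5 * (lo + hi), 0.5 * (hi - lo) * flattened_fraction
    sel = (p.positions >= c - hw) & (p.positions <= c + hw)
    vals = p.values[sel]
    if vals.size == 0:
        raise ValueError("flattened region contains no samples")
    if vals.min() <= 0:
        raise ValueError("flattened region contains zero dose")
    return float(100.0 * (vals.max() - vals.min()) / (vals.max() + vals.min()))


def gamma_pass_rate(eval_map: DoseMap, ref_map: DoseMap,
                    dose_crit: float = 3.0, dta_mm: float = 3.0,
                    threshold: float = 10.0,
                    local: bool = True) -> GammaResult:
    """Gamma index of an evaluated dose map against a reference.

    ``dose_crit`` is the dose criterion in percent (local normalization by
    default, global CAX normalization behind the flag), ``dta_mm`` the
    distance-to-agreement in mm, ``threshold`` the inclusion cut in
    percent of the reference central-axis dose.
    """
    dta = dta_mm / 10.0  # cm
    cax = ref_map.cax_value()
    if cax <= 0:
        raise ValueError("reference has no central-axis dose")
    cut = threshold / 100.0 * cax

    # fine reference lattice at <= dta/10 steps, commensurate with eval
    res_e = eval_map.resolution
    sub = int(np.ceil(res_e / (dta / 10.0)))
    fine = res_e / sub
    interp = RegularGridInterpolator((ref_map.y, ref_map.x), ref_map.values,
                                     bounds_error=False, fill_value=np.nan)
    yf = np.arange(ref_map.y[0], ref_map.y[-1] + fine / 2, fine)
    xf = np.arange(ref_map.x[0], ref_map.x[-1] + fine / 2, fine)
    YF, XF = np.meshgrid(yf, xf, indexing="ij")
    ref_fine = interp(np.stack([YF.ravel(), XF.ravel()], axis=1)).reshape(YF.shape)

    ey, ex = np.meshgrid(eval_map.y, eval_map.x, indexing="ij")
    include = None
    # reference sampled at the eval lattice decides inclusion
    ref_at_eval = interp(np.stack([ey.ravel(), ex.ravel()], axis=1)).reshape(ey.shape)
    include = np.isfinite(ref_at_eval) & (ref_at_eval >= cut)
    if not include.any():
        raise ValueError("all voxels fall below the dose threshold")

    iy = np.round((ey[include] - yf[0]) / fine).astype(int)
    ix = np.round((ex[include] - xf[0]) / fine).astype(int)
    dvals = eval_map.values[include]

    radius = int(np.ceil(3.0 * dta / fine))
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            r2 = (dy * dy + dx * dx) * fine * fine
            if r2 <= (3.0 * dta) ** 2:
                offs.append((r2, dy, dx))
    offs.sort()

    ny, nx = ref_fine.shape
    best = np.full(dvals.shape, np.inf)
    active = np.ones(dvals.shape, dtype=bool)
    for r2, dy, dx in offs:
        dist2 = r2 / (dta * dta)
        # any point already at or below this spatial term cannot improve
        active &= best > dist2
        if not active.any():
            break
        jy = iy[active] + dy
        jx = ix[active] + dx
        ok = (jy >= 0) & (jy < ny) & (jx >= 0) & (jx < nx)
        rv = np.full(jy.shape, np.nan)
        rv[ok] = ref_fine[jy[ok], jx[ok]]
        denom = (dose_crit / 100.0) * np.where(local, np.abs(rv), cax)
        with np.errstate(invalid="ignore", divide="ignore"):
            g2 = ((dvals[active] - rv) / denom) ** 2 + dist2
        g2 = np.where(np.isfinite(g2), g2, np.inf)
        idx = np.flatnonzero(active)
        better = g2 < best[idx]
        best[idx[better]] = g2[better]

    gamma = np.full(eval_map.values.shape, np.nan)
    gamma[include] = np.sqrt(best)
    n_inc = int(include.sum())
    pass_frac = 100.0 * float((gamma[include] <= 1.0).sum()) / n_inc
    return GammaResult(gamma=gamma, pass_fraction=pass_frac, n_included=n_inc,
                       criteria={"dose_crit_pct": dose_crit, "dta_mm": dta_mm,
                                 "threshold_pct": threshold,
                                 "normalization": "local" if local else "global"})


@dataclass
class DipResult:
    """Maximum local dip depth of two profiles (% of CAX) and the change."""

    depth_without: float
    depth_with: float

    @property
    def difference(self) -> float:
        """Positive when the dips were reduced."""
        return self.depth_without - self.depth_with


def dip_depth(p: Profile, min_width: float = 0.5,
              max_width: float = 3.0, noise_level: float = 1e-3,
              dose_floor: float = 0.2) -> float:
    """Maximum local dip depth (% of CAX) of a normalized profile.

    A dip is the deficit of the profile against its local-maxima envelope
    (morphological closing with a ``max_width`` window); contiguous
    deficit features narrower than ``min_width`` are treated as grid
    noise and ignored, as are features whose envelope lies below
    ``dose_floor`` of the CAX (the out-of-field tail carries no
    meaningful dips).
    """
    dx = float(np.median(np.diff(p.positions)))
    size = max(3, int(round(max_width / dx)) | 1)
    env = ndimage.grey_closing(p.values, size=size, mode="nearest")
    deficit = env - p.values
    sig = (deficit > noise_level) & (env >= dose_floor)
    lbl, n = ndimage.label(sig)
    depth = 0.0
    for k in range(1, n + 1):
        run = lbl == k
        if run.sum() * dx >= min_width:
            depth = max(depth, float(deficit[run].max()))
    return 100.0 * depth


def tng_dip_metric(p_without: Profile, p_with: Profile,
                   min_width: float = 0.5) -> DipResult:
    """Dip depths of profiles optimized without/with T&G control.

    A positive ``difference`` means the T&G penalty reduced the
    underdose stripes.
    """
    if (p_without.positions.shape != p_with.positions.shape
            or not np.allclose(p_without.positions, p_with.positions)):
        raise ValueError("profiles must share the same positions")
    return DipResult(depth_without=dip_depth(p_without, min_width=min_width),
                     depth_with=dip_depth(p_with, min_width=min_width))
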