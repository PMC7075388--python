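"""Field contours: built-in parametric shapes and plain-text polygon I/O."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

BUILTIN_NAMES = (
    "square",
    "rectangle",
    "hourglass",
    "mantle_like",
    "whole_brain_like",
    "spine_asym",
)


@dataclass(frozen=True)
class FieldContour:
    """Closed simple polygon in isocenter-plane coordinates (cm).

    Vertices are stored open (the closing edge is implicit). The beam
    central axis is at (0, 0).
    """

    vertices: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs an (n, 2) array with n >= 3")
        object.__setattr__(self, "vertices", v)
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError(f"contour {self.name!r} is not a simple polygon")
        if poly.area <= 0:
            raise ValueError(f"contour {self.name!r} has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in cm."""
        return self.polygon.bounds


def builtin_contour(name: str, **params) -> FieldContour:
    """Return one of the built-in parametric field shapes.

    ``square(side)`` and ``rectangle(width, height)`` are axis-centered
    boxes. ``hourglass`` has a smooth concave waist, ``mantle_like`` a
    concave inferior notch (stand-ins for clinically concave fields that
    provoke tongue-and-groove mismatch between adjacent rows),
    ``whole_brain_like`` is a rounded cranium-like outline and
    ``spine_asym`` a laterally offset narrow rectangle.
    """
    if name not in BUILTIN_NAMES:
        raise ValueError(f"unknown contour {name!r}; choose from {BUILTIN_NAMES}")
    maker = {
        "square": _square,
        "rectangle": _rectangle,
        "hourglass": _hourglass,
        "mantle_like": _mantle_like,
        "whole_brain_like": _whole_brain_like,
        "spine_asym": _spine_asym,
    }[name]
    return maker(**params)


def _square(side: float = 10.0) -> FieldContour:
    if side <= 0:
        raise ValueError("square side must be positive")
    h = side / 2.0
    verts = [(-h, -h), (h, -h), (h, h), (-h, h)]
    return FieldContour(np.array(verts), name=f"square_{side:g}")


def _rectangle(width: float = 15.0, height: float = 6.0,
               center: tuple[float, float] = (0.0, 0.0)) -> FieldContour:
    if width <= 0 or height <= 0:
        raise ValueError("rectangle dimensions must be positive")
    cx, cy = center
    hw, hh = width / 2.0, height / 2.0
    verts = [(cx - hw, cy - hh), (cx + hw, cy - hh),
             (cx + hw, cy + hh), (cx - hw, cy + hh)]
    return FieldContour(np.array(verts), name=f"rectangle_{width:g}x{height:g}")


def _hourglass(width: float = 12.0, height: float = 14.0,
               waist: float = 4.0) -> FieldContour:
    """Concave waist narrowing smoothly from ``width`` to ``waist`` at y=0."""
    if width <= 0 or height <= 0 or waist <= 0:
        raise ValueError("hourglass dimensions must be positive")
    if waist > width:
        raise ValueError("waist must not exceed width")
    ys = np.linspace(-height / 2.0, height / 2.0, 41)
    half = width / 2.0 - (width - waist) / 2.0 * np.cos(np.pi * ys / height) ** 2
    right = np.column_stack([half, ys])
    left = np.column_stack([-half, ys])[::-1]
    return FieldContour(np.vstack([right, left]), name="hourglass")


def _mantle_like(width: float = 16.0, height: float = 12.0,
                 notch_width: float = 8.0, notch_depth: float = 7.0) -> FieldContour:
    """Mantle-field stand-in: a box with a concave inferior-corner scoop.

    The scoop removes the lower-left corner along a curved boundary, so the
    rows of the lower half open over laterally offset intervals. A centered
    inferior notch would split rows into two disjoint apertures (out of
    scope); a corner scoop keeps one interval per row while still forcing
    the adjacent-row trajectory mismatch that provokes tongue-and-groove
    underdose stripes.
    """
    if min(width, height, notch_width, notch_depth) <= 0:
        raise ValueError("mantle dimensions must be positive")
    if notch_width >= width or notch_depth >= height:
        raise ValueError("notch must be smaller than the field")
    hw, hh = width / 2.0, height / 2.0
    # scoop from (-hw, -hh + depth) down to (-hw + width_n, -hh), bulging
    # into the field (concave corner)
    t = np.linspace(0.0, 1.0, 25)
    sx = -hw + notch_width * np.sin(np.pi * t / 2.0)
    sy = -hh + notch_depth * np.cos(np.pi * t / 2.0)
    verts = ([(-hw, hh), (-hw, -hh + notch_depth)]
             + [(x, y) for x, y in zip(sx[1:-1], sy[1:-1])]
             + [(-hw + notch_width, -hh), (hw, -hh), (hw, hh)])
    return FieldContour(np.array(verts), name="mantle_like")


def _whole_brain_like(width: float = 16.0, height: float = 12.0) -> FieldContour:
    """Rounded cranium-like outline (superellipse)."""
    if width <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    t = np.linspace(0, 2 * np.pi, 73)[:-1]
    n = 3.0  # superellipse exponent: between ellipse and box
    x = width / 2.0 * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / n)
    y = height / 2.0 * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / n)
    return FieldContour(np.column_stack([x, y]), name="whole_brain_like")


def _spine_asym(width: float = 6.0, height: float = 15.0,
                offset: float = 2.0) -> FieldContour:
    """Narrow field offset laterally from the central axis."""
    return FieldContour(
        _rectangle(width, height, center=(offset, 0.0)).vertices,
        name="spine_asym",
    )


def write_contour(contour: FieldContour, path) -> None:
    """Write a two-column (x_cm, y_cm) plain-text polygon file."""
    path = Path(path)
    header = f"# flatbeam contour: {contour.name}\n# x_cm,y_cm\n"
    body = "\n".join(f"{x:.6f},{y:.6f}" for x, y in contour.vertices)
    path.write_text(header + body + "\n")


def read_contour(path, name: str | None = None) -> FieldContour:
    """Read a two-column plain-text/CSV polygon (closed implicitly)."""
    path = Path(path)
    rows = []
    tag = name
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if tag is None and "contour:" in line:
                tag = line.split("contour:", 1)[1].strip()
            continue
        parts = line.replace(",", " ").split()
        rows.append((float(parts[0]), float(parts[1])))
    verts = np.array(rows)
    # drop an explicit closing vertex if present
    if len(verts) > 3 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    return FieldContour(verts, name=tag or path.stem)
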