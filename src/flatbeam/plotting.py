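"""Matplotlib views of trajectories, fluence maps and profiles."""
from __future__ import annotations

from .dose import DoseMap
from .metrics import extract_profile
from .results import FluenceTimeMap, TrajectorySolution


def plot_trajectories(sol: TrajectorySolution, rows=None, ax=None):
    """Leaf-tip position vs beam-on time for the selected rows.

    The classic sliding-window picture: each leaf pair draws two
    monotone staircase curves; the horizontal distance between them at a
    position is that bixel's exposure time.
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    rows = range(sol.n_rows) if rows is None else rows
    for i in rows:
        row = sol.rows[i]
        tt, pp = row.trailing_curve(sol.t_total)
        ax.plot(tt, pp, color="C0", lw=1)
        tt, pp = row.leading_curve(sol.t_total)
        ax.plot(tt, pp, color="C1", lw=1)
    ax.set_xlabel("beam-on time (s)")
    ax.set_ylabel("leaf tip position (cm)")
    ax.set_title("leaf trajectories (blue: trailing, orange: leading)")
    return ax


def plot_fluence(fmap: FluenceTimeMap, ax=None, mu: bool = True):
    """Per-bixel fluence (MU) or exposure time as an image."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    grid = fmap.grid
    bw = grid.bixel_width
    x0 = fmap.col0 * bw
    extent = [x0, x0 + fmap.t.shape[1] * bw, grid.y_min, grid.y_max]
    data = fmap.x if mu else fmap.t
    im = ax.imshow(data, origin="lower", extent=extent, aspect="equal",
                   interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="MU" if mu else "s")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    return ax


def plot_profiles(dose: DoseMap, reference: DoseMap | None = None,
                  axis: str = "crossline", ax=None):
    """Normalized central-axis profile, optionally against the reference."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    p = extract_profile(dose, axis)
    ax.plot(p.positions, p.values, label="optimized")
    if reference is not None:
        pr = extract_profile(reference, axis)
        ax.plot(pr.positions, pr.values, "--", label="flat reference")
    ax.set_xlabel(f"{axis} position (cm)")
    ax.set_ylabel("relative dose")
    ax.legend()
    return ax
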