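"""End-to-end runs: configuration, the full field pipeline, weight sweeps
and fixture generation.

``run_field`` executes rasterize -> dose influence -> flat reference ->
build/solve -> validate -> control points -> reconstruct -> metrics and
writes the plan, a metrics report and the resolved configuration, so
every run directory is self-describing and bit-reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .beam import BeamModel, flat_reference_beam
from .contours import BUILTIN_NAMES, builtin_contour, read_contour, write_contour
from .delivery import reconstruct_fluence, write_plan
from .dose import build_dose_influence, reference_flat_dose
from .grid import rasterize_contour
from .machine import MachineSpec, default_machine_spec
from .metrics import extract_profile, gamma_pass_rate, iec_flatness
from .model import LeafTrajectoryModel, Weights
from .qp import SolverOptions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Complete description of one optimization run.

    ``field`` is a built-in shape name or a contour file path;
    ``shape_params`` feed the built-in generator. Weight ratios follow
    the published operating point (lambda1/lambda2 = 1000; when T&G
    control is on, lambda1/lambda3 = 0.1).
    """

    field: str = "square"
    shape_params: dict = dc_field(default_factory=dict)
    machine: dict = dc_field(default_factory=dict)
    bixel_width: float = 0.2
    dose_resolution: float = 0.2
    margin: float = 3.0
    lambda1: float = 1.0
    l1_over_l2: float = 1000.0
    tng: bool = False
    l1_over_l3: float = 0.1
    prescription_mu: float = 35.0
    n_control_points: int = 50
    solver: dict = dc_field(default_factory=dict)
    out_dir: str | None = None

    # --- resolution ----------------------------------------------------
    def machine_spec(self) -> MachineSpec:
        return default_machine_spec().replace(**self.machine)

    def weights(self) -> Weights:
        return Weights.from_ratios(
            self.lambda1, self.l1_over_l2,
            self.l1_over_l3 if self.tng else None)

    def contour(self):
        if self.field in BUILTIN_NAMES:
            return builtin_contour(self.field, **self.shape_params)
        return read_contour(self.field)

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def field_bounds(grid):
    """(crossline, inline) field bounds (cm) through the central axes.

    Crossline: the open interval of the row crossing y=0 (nearest row
    center if no row contains y=0). Inline: the y-extent of the rows
    whose interval contains x=0 (all rows if none does).
    """
    rows = grid.rows
    crossing = [r for r in rows if r.y_low <= 0.0 <= r.y_high]
    row = crossing[0] if crossing else min(rows, key=lambda r: abs(r.y_center))
    cross = (row.x_start, row.x_end)
    on_axis = [r for r in rows if r.x_start <= 0.0 <= r.x_end] or rows
    inline = (min(r.y_low for r in on_axis), max(r.y_high for r in on_axis))
    return cross, inline


def run_field(config: RunConfig, solve: bool = True) -> dict:
    """Execute the full pipeline for one field; returns the run bundle.

    The bundle holds the model, results, control points, reconstructed
    fluence and the metrics dict. When ``config.out_dir`` is set, the
    plan (JSON + CSV), metrics report, solution summary and resolved
    config are written there. Raises RuntimeError if the optimized
    trajectories fail constraint validation.
    """
    t_start = time.perf_counter()
    machine = config.machine_spec()
    contour = config.contour()
    stage_times: dict[str, float] = {}

    def stage(name):
        stage_times[name] = time.perf_counter() - t_start
        log.info("stage %s done at %.1f s", name, stage_times[name])

    grid = rasterize_contour(contour, machine, config.bixel_width)
    stage("rasterize")
    beam = BeamModel(mode="fff")
    influence = build_dose_influence(grid, beam,
                                     resolution=config.dose_resolution,
                                     margin=config.margin)
    stage("influence")
    reference = reference_flat_dose(grid, flat_reference_beam(kernel=beam.kernel),
                                    resolution=config.dose_resolution,
                                    margin=config.margin)
    stage("reference")
    model = LeafTrajectoryModel(grid, influence, reference,
                                weights=config.weights(), machine=machine,
                                prescription_mu=config.prescription_mu)
    stage("build")
    results = model.fit(config.solver_options())
    stage("solve")
    log.info("solver: %s in %d iterations (%.1f s wall)",
             results.qp.status, results.qp.iterations, results.qp.wall_time)

    report = results.validate()
    stage("validate")
    if not report.passed:
        raise RuntimeError("optimized trajectories failed constraint "
                           "validation:\n" + report.summary())

    cps = results.control_points(config.n_control_points)
    recon = reconstruct_fluence(cps, grid)
    stage("control_points")

    dose = results.dose()
    cross_b, in_b = field_bounds(grid)
    p_cross = extract_profile(dose, "crossline")
    p_in = extract_profile(dose, "inline")
    gamma = gamma_pass_rate(dose, reference_scaled(model))
    stage("metrics")

    metrics = {
        "field": grid.name or config.field,
        "flatness_crossline_pct": iec_flatness(p_cross, cross_b),
        "flatness_inline_pct": iec_flatness(p_in, in_b),
        "gamma_pass_pct": gamma.pass_fraction,
        "gamma_criteria": gamma.criteria,
        "delivery_time_s": results.t_total,
        "mu_total": results.mu_total,
        "tng_sum_mu": results.tng().total,
        "solver_iterations": results.qp.iterations,
        "solver_wall_s": results.qp.wall_time,
        "objective": results.objective_breakdown()["total"],
        "max_reconstruction_error_s": float(
            np.abs(recon.t - results.fluence().t).max()),
    }

    bundle = {"config": config, "grid": grid, "model": model,
              "results": results, "report": report, "cps": cps,
              "reconstructed": recon, "dose": dose, "metrics": metrics,
              "stage_times": stage_times}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        write_plan(cps, out / "plan.json", "json")
        write_plan(cps, out / "plan.csv", "csv")
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        (out / "summary.txt").write_text(results.summary() + "\n")
        dose.to_csv(out / "dose.csv")
        log.info("run artifacts written to %s", out)
    return bundle


def reference_scaled(model: LeafTrajectoryModel):
    """The optimization target as a DoseMap (prescription units)."""
    from .dose import DoseMap
    return DoseMap(model._target_plane, model.reference.resolution,
                   model.reference.x0, model.reference.y0)


def sweep_weights(config: RunConfig, ratios, which: str = "lambda2"):
    """Re-run one field over a grid of weight ratios.

    ``which`` selects the swept term: ``lambda2`` varies lambda1/lambda2
    (delivery-time control), ``lambda3`` varies lambda1/lambda3 (T&G
    control, switching it on). Single-run failures are recorded and the
    sweep continues. Returns a pandas DataFrame.
    """
    import pandas as pd
    if which not in ("lambda2", "lambda3"):
        raise ValueError("which must be 'lambda2' or 'lambda3'")
    rows = []
    for ratio in ratios:
        if ratio <= 0:
            raise ValueError("ratios must be positive")
        c = RunConfig.from_dict(config.to_dict())
        c.out_dir = None
        if which == "lambda2":
            c.l1_over_l2 = ratio
        else:
            c.tng = True
            c.l1_over_l3 = ratio
        try:
            b = run_field(c)
            m = b["metrics"]
            rows.append({"ratio": ratio,
                         "gamma_pass_pct": m["gamma_pass_pct"],
                         "delivery_time_s": m["delivery_time_s"],
                         "tng_sum_mu": m["tng_sum_mu"],
                         "flatness_crossline_pct": m["flatness_crossline_pct"],
                         "flatness_inline_pct": m["flatness_inline_pct"],
                         "error": ""})
        except Exception as exc:  # noqa: BLE001 — sweep must continue
            log.warning("sweep point %s=%g failed: %s", which, ratio, exc)
            rows.append({"ratio": ratio, "error": str(exc)})
    return pd.DataFrame(rows)


FIXTURE_SHAPES = (
    ("square", {"side": 10.0}),
    ("square", {"side": 20.0}),
    ("square", {"side": 30.0}),
    ("square", {"side": 40.0}),
    ("rectangle", {"width": 15.0, "height": 6.0}),
    ("hourglass", {}),
    ("mantle_like", {}),
    ("whole_brain_like", {}),
    ("spine_asym", {}),
)


def generate_fixtures(out_dir) -> list[Path]:
    """Write contour files for the built-in shapes plus regression data.

    The regression instances are a one-row/4-bixel toy with the golden
    objective from the exhaustive lattice oracle, a two-row T&G toy with
    hand-computed strip times, and a coarse 10x10 run record.
    """
    from .bruteforce import TinyRowProblem, exhaustive_lattice_search
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, params in FIXTURE_SHAPES:
        c = builtin_contour(name, **params)
        p = out / f"contour_{c.name}.csv"
        write_contour(c, p)
        written.append(p)

    machine = default_machine_spec()
    tiny = TinyRowProblem(n_bixels=4, target=(3.0, 3.0, 3.0, 3.0),
                          machine=machine)
    obj, times = exhaustive_lattice_search(tiny, t_max=1.0, n_steps=20)
    p = out / "tiny_one_row.json"
    p.write_text(json.dumps({
        "n_bixels": tiny.n_bixels, "target": list(tiny.target),
        "bixel_width": tiny.bixel_width, "lambda1": tiny.lambda1,
        "lambda2": tiny.lambda2, "lattice_t_max": 1.0, "lattice_steps": 20,
        "lattice_objective": obj,
        "lattice_times": {str(k): v for k, v in times.items()},
    }, indent=1))
    written.append(p)

    # two-row T&G toy: row 1's trailing leaf lags row 0 by exactly 2 s
    p = out / "tiny_two_row_tng.json"
    p.write_text(json.dumps({
        "description": "adjacent trailing leaves offset by 2 s -> "
                       "t_LTG = 2 s at every shared bixel",
        "lag_s": 2.0, "expected_t_ltg_s": 2.0, "expected_t_rtg_s": 0.0,
    }, indent=1))
    written.append(p)

    cfg = RunConfig(field="square", shape_params={"side": 10.0},
                    bixel_width=0.2, dose_resolution=0.4)
    b = run_field(cfg)
    p = out / "coarse_10x10.json"
    p.write_text(json.dumps({
        "config": cfg.to_dict(),
        "objective": b["results"].qp.objective,
        "delivery_time_s": b["results"].t_total,
        "metrics": {k: v for k, v in b["metrics"].items()
                    if isinstance(v, (int, float, str))},
    }, indent=1))
    written.append(p)
    return written
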