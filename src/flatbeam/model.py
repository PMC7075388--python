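"""The direct leaf trajectory optimization model.

Variables are the boundary arrival/departure times of both leaves of
every active row plus the shared total beam-on time ``T`` (the trailing
leaves' final departure, identical for all rows so the beam switches off
synchronously). The per-bixel exposure time is the trapezoid average of
the four surrounding crossing times, fluence is ``DR * t``, and the dose
is the influence operator applied to the fluence, giving the convex
program

    minimize   lambda1 * sum_i (d_i - d_i^D)^2
             + lambda2 * T
             + lambda3 * sum |x_LTG| + |x_RTG|        (epigraph auxiliaries)
    subject to ordering, leaf-speed, minimum-gap, overtravel (as index
               bounds), carriage-span (flagged pairs only) and beam-off
               synchronization constraints, all linear.

The minimum gap is enforced by *two* index-shifted time families,
``r_out[j] <= l_out[j-G]`` and ``r_in[j] <= l_in[j-G]`` with
``G = min_gap / bixel_width``; together they are equivalent to
``gap >= min_gap`` at every instant of the piecewise-linear delivery,
not only at bixel boundaries. Leaf speed enters as
``in[j+1] - out[j] >= bixel_width / v_max`` per leaf, the linear form
used throughout the sliding-window trajectory literature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .beam import BeamModel, flat_reference_beam
from .contours import FieldContour, builtin_contour
from .dose import DoseInfluence, DoseMap, build_dose_influence, reference_flat_dose
from .grid import FieldGrid, detect_carriage_pairs, leaf_travel_ranges, rasterize_contour
from .machine import MachineSpec, default_machine_spec
from .qp import QPSolution, SolverOptions, solve_qp
from .results import (ConstraintReport, FluenceTimeMap, RowTrajectory,
                      TnGMap, TrajectorySolution, effective_time, tng_times,
                      validate_solution)

#: problems with at most this many bixels use an exact sparse Hessian and
#: direct Newton solves; larger ones go matrix-free with PCG
EXACT_HESSIAN_BIXELS = 400


@dataclass(frozen=True)
class Weights:
    """Objective weights: dose fidelity, delivery time, T&G penalty.

    Defaults follow the published operating point: the delivery-time
    weight is lambda1/1000 and the T&G weight, when enabled, is
    lambda1/0.1 (i.e. 10x lambda1).
    """

    lambda1: float = 1.0
    lambda2: float = 1.0 / 1000.0
    lambda3: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise ValueError("lambda1 must be strictly positive")
        if self.lambda2 < 0 or self.lambda3 < 0:
            raise ValueError("lambda2 and lambda3 must be non-negative")

    @staticmethod
    def from_ratios(lambda1: float = 1.0, l1_over_l2: float = 1000.0,
                    l1_over_l3: float | None = None) -> "Weights":
        l3 = 0.0 if l1_over_l3 is None else lambda1 / l1_over_l3
        return Weights(lambda1=lambda1, lambda2=lambda1 / l1_over_l2, lambda3=l3)


class _Sym:
    """A symbolic affine time value: sum of (column, coefficient) plus const."""

    __slots__ = ("terms", "const")

    def __init__(self, terms=(), const=0.0):
        self.terms = list(terms)
        self.const = const

    @property
    def is_const(self) -> bool:
        return not self.terms


class LeafTrajectoryModel:
    """Convex trajectory program for one field; ``fit`` solves it.

    Parameters
    ----------
    grid : FieldGrid
        Rasterized field.
    influence : DoseInfluence
        Dose influence of the modulated (FFF) beam.
    reference : DoseMap
        Desired dose, CAX-normalized, on the same plane as ``influence``.
    weights : Weights
    prescription_mu : float
        Fluence scale (MU at the CAX) the normalized reference is mapped
        to before optimization. Must exceed the sliding-window fluence
        floor ``min_gap / v_max * DR``.
    """

    def __init__(self, grid: FieldGrid, influence: DoseInfluence,
                 reference: DoseMap, weights: Weights | None = None,
                 machine: MachineSpec | None = None,
                 prescription_mu: float = 35.0):
        self.grid = grid
        self.influence = influence
        self.reference = reference
        self.weights = weights or Weights()
        self.machine = machine or grid.machine
        self.prescription_mu = float(prescription_mu)
        if reference.values.shape != influence.plane_shape:
            raise ValueError("reference dose and influence planes differ "
                             f"({reference.values.shape} vs {influence.plane_shape})")
        if abs(reference.resolution - influence.resolution) > 1e-9:
            raise ValueError("reference dose and influence resolutions differ")
        floor_mu = (self.machine.min_gap / self.machine.v_max
                    * self.machine.dose_rate_mod_per_s)
        if self.prescription_mu <= 2.0 * floor_mu:
            raise ValueError(
                f"prescription_mu={prescription_mu} is at or below the "
                f"sliding-window fluence floor ({floor_mu:.2f} MU/bixel); "
                "the flat target would be unreachable")
        self._build()

    # ------------------------------------------------------------------
    @classmethod
    def from_field(cls, field, machine: MachineSpec | None = None,
                   bixel_width: float = 0.2, dose_resolution: float = 0.2,
                   margin: float = 3.0, weights: Weights | None = None,
                   beam: BeamModel | None = None,
                   prescription_mu: float = 35.0,
                   **shape_params) -> "LeafTrajectoryModel":
        """Build the model straight from a contour (or built-in shape name)."""
        machine = machine or default_machine_spec()
        if isinstance(field, str):
            field = builtin_contour(field, **shape_params)
        if not isinstance(field, FieldContour):
            raise TypeError("field must be a FieldContour or a shape name")
        grid = rasterize_contour(field, machine, bixel_width)
        beam = beam or BeamModel(mode="fff")
        influence = build_dose_influence(grid, beam, resolution=dose_resolution,
                                         margin=margin)
        reference = reference_flat_dose(
            grid, flat_reference_beam(kernel=beam.kernel),
            resolution=dose_resolution, margin=margin)
        return cls(grid, influence, reference, weights=weights,
                   machine=machine, prescription_mu=prescription_mu)

    # ------------------------------------------------------------------
    def _build(self) -> None:
        grid, machine = self.grid, self.machine
        bw = grid.bixel_width
        G = int(round(machine.min_gap / bw))
        if abs(machine.min_gap / bw - G) > 1e-9 or G < 1:
            raise ValueError("min_gap must be a positive integer multiple "
                             "of the bixel width")
        self.gap_index = G
        dt_min = bw / machine.v_max
        col0 = int(round(grid.x_min / bw))
        n_cols = int(round((grid.x_max - grid.x_min) / bw))
        self.col0, self.n_cols = col0, n_cols

        ts, te, ls, le = leaf_travel_ranges(grid, machine)
        self._layout = []
        off = 0
        for i in range(grid.n_rows):
            J = grid.n_bixels(i)
            x0 = grid.rows[i].x_start
            a = int(round((ls[i] - x0) / bw))
            e = int(round((te[i] - x0) / bw))
            a = max(a, G)
            e = min(e, J - G)
            nro = nri = J - a
            nlo = nli = e
            self._layout.append(dict(J=J, a=a, e=e, off=off,
                                     nro=nro, nri=nri, nlo=nlo, nli=nli))
            off += nro + nri + nlo + nli
        self.T_col = off
        n_core = off + 1

        # ---- symbolic time accessors (local boundary index) -----------
        def r_out(i, j):
            L = self._layout[i]
            if j < L["a"]:
                return _Sym(const=0.0)
            if j >= L["J"]:
                return _Sym([(self.T_col, 1.0)])
            return _Sym([(L["off"] + (j - L["a"]), 1.0)])

        def r_in(i, j):
            L = self._layout[i]
            if j <= L["a"]:
                return _Sym(const=0.0)
            if j > L["J"]:
                return _Sym([(self.T_col, 1.0)])
            return _Sym([(L["off"] + L["nro"] + (j - L["a"] - 1), 1.0)])

        def l_out(i, j):
            L = self._layout[i]
            if j < 0:
                return _Sym(const=0.0)
            if j >= L["e"]:
                return _Sym([(self.T_col, 1.0)])
            return _Sym([(L["off"] + L["nro"] + L["nri"] + j, 1.0)])

        def l_in(i, j):
            L = self._layout[i]
            if j <= 0:
                return _Sym(const=0.0)
            if j > L["e"]:
                return _Sym([(self.T_col, 1.0)])
            return _Sym([(L["off"] + L["nro"] + L["nri"] + L["nlo"]
                          + (j - 1), 1.0)])

        self._sym = dict(r_out=r_out, r_in=r_in, l_out=l_out, l_in=l_in)

        # ---- carriage preprocessing ------------------------------------
        # Pairwise span constraints are generated per flagged pair; when a
        # wide sweep flags nearly every pair (O(n^2 J) rows) they are
        # replaced by the equivalent per-boundary envelope form
        #   f(n, g) <= u_g <= f(m, g + S)   for all involved rows n, m,
        # which has the same feasible set (unflagged pairs cannot violate
        # the span by the preprocessing argument) at O(n J) rows.
        S = int(np.floor(machine.bank_span / bw + 1e-9))
        flags = detect_carriage_pairs(grid, machine)
        self.carriage_flags = flags
        row_off = [int(round(grid.rows[i].x_start / bw))
                   for i in range(grid.n_rows)]
        g_lo = min(row_off)
        g_hi = max(row_off[i] + self._layout[i]["J"] for i in range(grid.n_rows))
        n_pairwise = sum(self._layout[fl.n]["J"] + 1 for fl in flags)
        self._carriage_aggregated = n_pairwise > 20000
        self._carr_u: dict = {}
        self._carr_rows = {
            bank: sorted({fl.n for fl in flags if fl.bank == bank}
                         | {fl.m for fl in flags if fl.bank == bank})
            for bank in ("left", "right")}
        if self._carriage_aggregated:
            # an envelope variable u_g is useful only where it has both a
            # genuine lower bound f(n, g) and a genuine upper bound
            # f(m, g + S); parked boundaries carry no real constraint
            for bank in ("left", "right"):
                real_g = set()
                for n in self._carr_rows[bank]:
                    L = self._layout[n]
                    lo, hi = ((0, L["e"] - 1) if bank == "left"
                              else (L["a"], L["J"] - 1))
                    real_g.update(range(row_off[n] + lo, row_off[n] + hi + 1))
                for g in sorted(real_g):
                    if g + S in real_g:
                        self._carr_u[(bank, g)] = n_core + len(self._carr_u)
        n_carr = len(self._carr_u)
        aux_base = n_core + n_carr

        # ---- constraints ----------------------------------------------
        rows_A, cols_A, vals_A, rhs = [], [], [], []

        def add(expr_terms, limit):
            r = len(rhs)
            for col, coef in expr_terms:
                rows_A.append(r)
                cols_A.append(col)
                vals_A.append(coef)
            rhs.append(limit)

        def add_le(sa: _Sym, sb: _Sym, slack: float = 0.0):
            """sa <= sb - slack, skipping structurally trivial cases."""
            terms = {}
            for col, coef in sa.terms:
                terms[col] = terms.get(col, 0.0) + coef
            for col, coef in sb.terms:
                terms[col] = terms.get(col, 0.0) - coef
            terms = {c: v for c, v in terms.items() if v != 0.0}
            limit = sb.const - sa.const - slack
            if not terms:
                return
            add(list(terms.items()), limit)

        T = _Sym([(self.T_col, 1.0)])
        zero = _Sym(const=0.0)
        add_le(zero, T)  # T >= 0
        for i in range(grid.n_rows):
            L = self._layout[i]
            a, e, J = L["a"], L["e"], L["J"]
            if L["nro"]:
                add_le(zero, r_out(i, a))
                add_le(r_in(i, J), T)
            for j in range(a + 1, J):
                add_le(r_in(i, j), r_out(i, j))
            for j in range(a, J):
                add_le(r_out(i, j), r_in(i, j + 1), slack=dt_min)
            if e >= 1:
                add_le(zero, l_out(i, 0))
                add_le(l_in(i, e), T)
            for j in range(1, e):
                add_le(l_in(i, j), l_out(i, j))
            for j in range(0, e):
                add_le(l_out(i, j), l_in(i, j + 1), slack=dt_min)
            for j in range(a, J):
                add_le(r_out(i, j), l_out(i, j - G))
            for j in range(a + 1, J + 1):
                add_le(r_in(i, j), l_in(i, j - G))

        # carriage-span constraints, only for flagged same-bank pairs.
        # Constraints are generated only between genuine trajectory
        # variables: comparisons against parked boundaries (constants 0
        # or the shared T) are either trivially slack or ill-defined
        # "departure times" of a leaf that never visits the boundary —
        # and pinning envelope variables against T makes the program
        # dual-degenerate. The positional span itself is re-checked on
        # the delivered motion by validate_solution.
        def is_real(sym: _Sym) -> bool:
            return (not sym.is_const
                    and not (len(sym.terms) == 1
                             and sym.terms[0][0] == self.T_col))

        carr_start = len(rhs)
        if self._carriage_aggregated:
            for bank in ("left", "right"):
                fn = l_out if bank == "left" else r_out
                for n in self._carr_rows[bank]:
                    Ln = self._layout[n]
                    for g in range(row_off[n], row_off[n] + Ln["J"] + 1):
                        sym = fn(n, g - row_off[n])
                        if not is_real(sym):
                            continue
                        if (bank, g) in self._carr_u:
                            add_le(sym, _Sym([(self._carr_u[(bank, g)], 1.0)]))
                        if (bank, g - S) in self._carr_u:
                            add_le(_Sym([(self._carr_u[(bank, g - S)], 1.0)]),
                                   sym)
        else:
            for fl in flags:
                fn = l_out if fl.bank == "left" else r_out
                Ln = self._layout[fl.n]
                for g in range(row_off[fl.n], row_off[fl.n] + Ln["J"] + 1):
                    sa = fn(fl.n, g - row_off[fl.n])
                    sb = fn(fl.m, g + S - row_off[fl.m])
                    if is_real(sa) and is_real(sb):
                        add_le(sa, sb)

        carr_end = len(rhs)

        # T&G epigraph auxiliaries
        self.n_core = n_core
        self._tng_pairs = [(i, i + 1) for i in range(grid.n_rows - 1)
                           if grid.rows[i + 1].index == grid.rows[i].index + 1]
        self._tng_aux = []
        n_aux = 0
        if self.weights.lambda3 > 0:
            for (i, k) in self._tng_pairs:
                for bank in ("L", "R"):
                    for c in range(n_cols):
                        expr = self._tng_expr(i, k, c, bank)
                        if expr.is_const:
                            continue
                        s_col = aux_base + n_aux
                        n_aux += 1
                        # +expr - s <= 0 and -expr - s <= 0
                        add(expr.terms + [(s_col, -1.0)], -expr.const)
                        add([(col, -v) for col, v in expr.terms]
                            + [(s_col, -1.0)], expr.const)
                        self._tng_aux.append((i, k, c, bank, s_col))
        self.n_aux = n_aux
        self.n_variables = aux_base + n_aux

        self.A = sparse.csr_matrix(
            (vals_A, (rows_A, cols_A)),
            shape=(len(rhs), self.n_variables))
        self.b = np.asarray(rhs, dtype=float)
        # the envelope rows couple every leaf row; keeping them out of the
        # Newton preconditioner avoids massive factorization fill-in
        if self._carriage_aggregated:
            self._precond_rows = np.ones(len(rhs), dtype=bool)
            self._precond_rows[carr_start:carr_end] = False
        else:
            self._precond_rows = None

        # ---- fluence map t = M v ---------------------------------------
        rows_M, cols_M, vals_M = [], [], []
        for i in range(grid.n_rows):
            L = self._layout[i]
            base = i * n_cols + (row_off[i] - col0)
            for j in range(L["J"]):
                r = base + j
                for sym, sign in ((l_out(i, j), 0.5), (l_in(i, j + 1), 0.5),
                                  (r_out(i, j), -0.5), (r_in(i, j + 1), -0.5)):
                    for col, coef in sym.terms:
                        rows_M.append(r)
                        cols_M.append(col)
                        vals_M.append(sign * coef)
        self.M = sparse.csr_matrix(
            (vals_M, (rows_M, cols_M)),
            shape=(grid.n_rows * n_cols, self.n_variables))

        # ---- objective --------------------------------------------------
        w = self.weights
        DR = self.machine.dose_rate_mod_per_s
        y = self.prescription_mu * self.reference.values
        self._target_plane = y
        adj = self.influence.adjoint(y).ravel()
        q = -2.0 * w.lambda1 * DR * (self.M.T @ adj)
        q[self.T_col] += w.lambda2
        if n_aux:
            q[n_core:] += w.lambda3 * DR
        self.q = q

        n_bix = grid.n_rows * n_cols
        self._exact = n_bix <= EXACT_HESSIAN_BIXELS
        scale = 2.0 * w.lambda1 * DR * DR
        if self._exact:
            H = self._gram_dense()
            P = (self.M.T @ sparse.csr_matrix(scale * H) @ self.M).tocsr()
            self.P_sparse, self.P_op = P, None
        else:
            Pt = (self.M.T @ self._gram_sparse_approx(scale) @ self.M).tocoo()
            # keep only within-row blocks plus the T arrowhead: the Newton
            # preconditioner then factorizes with near-block fill while the
            # constraint term (within-row + T by construction) stays exact
            bid = np.empty(self.n_variables, dtype=np.int64)
            for i, L in enumerate(self._layout):
                bid[L["off"]:L["off"] + L["nro"] + L["nri"]
                    + L["nlo"] + L["nli"]] = i
            bid[self.T_col] = -1
            bid[n_core:] = -1
            keep = ((bid[Pt.row] == bid[Pt.col])
                    | (Pt.row == self.T_col) | (Pt.col == self.T_col)
                    | (Pt.row == Pt.col))
            self.P_sparse = sparse.csr_matrix(
                (Pt.data[keep], (Pt.row[keep], Pt.col[keep])),
                shape=Pt.shape)
            M, MT = self.M, self.M.T.tocsr()
            shape = (grid.n_rows, n_cols)
            gram = self.influence.gram_apply

            def P_op(v):
                F = (M @ v).reshape(shape)
                return scale * (MT @ gram(F).ravel())

            self.P_op = P_op

    # ------------------------------------------------------------------
    def _tng_expr(self, i: int, k: int, c: int, bank: str) -> _Sym:
        """Signed T&G strip time for adjacent rows (i, k) at global col c."""
        col0 = self.col0
        off = [int(round(self.grid.rows[n].x_start / self.grid.bixel_width))
               for n in (i, k)]
        li, lk = c + col0 - off[0], c + col0 - off[1]
        s = self._sym
        terms: list = []
        const = 0.0
        if bank == "L":
            parts = ((s["l_out"](k, lk), 0.5), (s["l_in"](k, lk + 1), 0.5),
                     (s["l_out"](i, li), -0.5), (s["l_in"](i, li + 1), -0.5))
        else:
            parts = ((s["r_out"](i, li), 0.5), (s["r_in"](i, li + 1), 0.5),
                     (s["r_out"](k, lk), -0.5), (s["r_in"](k, lk + 1), -0.5))
        acc: dict = {}
        for sym, sign in parts:
            for col, coef in sym.terms:
                acc[col] = acc.get(col, 0.0) + sign * coef
            const += sign * sym.const
        terms = [(cc, vv) for cc, vv in acc.items() if vv != 0.0]
        return _Sym(terms, const)

    def _gram_dense(self) -> np.ndarray:
        """Exact fluence-level Gram matrix phi D'D phi (small problems)."""
        infl = self.influence
        n_bix = self.grid.n_rows * self.n_cols
        H = np.zeros((n_bix, n_bix))
        for wa, Ya, Xa in zip(infl.weights, infl.Yc, infl.Xc):
            for wb, Yb, Xb in zip(infl.weights, infl.Yc, infl.Xc):
                H += wa * wb * np.kron(Ya.T @ Yb, Xa.T @ Xb)
        phi = infl.phi.ravel()
        return phi[:, None] * H * phi[None, :]

    def _gram_sparse_approx(self, scale: float,
                            row_band: int = 1, col_band: int = 8):
        """Banded truncation of the Gram, used only as PCG preconditioner."""
        infl = self.influence
        H = None
        for wa, Ya, Xa in zip(infl.weights, infl.Yc, infl.Xc):
            for wb, Yb, Xb in zip(infl.weights, infl.Yc, infl.Xc):
                Gy = wa * wb * (Ya.T @ Yb)
                Gx = Xa.T @ Xb
                ny, nx = Gy.shape[0], Gx.shape[0]
                my = np.abs(np.subtract.outer(np.arange(ny), np.arange(ny))) <= row_band
                mx = np.abs(np.subtract.outer(np.arange(nx), np.arange(nx))) <= col_band
                term = sparse.kron(sparse.csr_matrix(Gy * my),
                                   sparse.csr_matrix(Gx * mx))
                H = term if H is None else H + term
        phi = sparse.diags(self.influence.phi.ravel())
        return (phi @ H @ phi) * scale

    # ------------------------------------------------------------------
    def initial_point(self) -> np.ndarray:
        """A strictly interior double-sweep trajectory (warm start)."""
        machine, grid = self.machine, self.grid
        dt_min = grid.bixel_width / machine.v_max
        delta, D0 = 0.05, 1.0
        rho = 2.0 * dt_min + delta + 0.02
        max_len = 1
        for L in self._layout:
            max_len = max(max_len, L["e"], L["J"] - L["a"])
        T0 = D0 + delta + rho * max_len
        v = np.zeros(self.n_variables)
        v[self.T_col] = T0
        for L in self._layout:
            a, e, J, off = L["a"], L["e"], L["J"], L["off"]
            if L["nro"]:
                c = min((T0 - D0 - delta) / max(e, 1) if e else np.inf,
                        0.98 * T0 / (J - a))
                c = max(c, dt_min + delta + 0.01)
                for j in range(a, J):            # r_out
                    v[off + (j - a)] = c * (j - a) + delta
                for j in range(a + 1, J + 1):    # r_in
                    v[off + L["nro"] + (j - a - 1)] = c * (j - a)
            if e >= 1:
                aa = (T0 - D0 - delta) / e
                for j in range(0, e):            # l_out
                    v[off + L["nro"] + L["nri"] + j] = D0 + aa * j + delta
                for j in range(1, e + 1):        # l_in
                    v[off + L["nro"] + L["nri"] + L["nlo"] + (j - 1)] = D0 + aa * j
        # park trailing-out at T exactly: l_out[e] is T by construction
        if self._carr_u:
            bw = self.grid.bixel_width
            row_off = [int(round(self.grid.rows[i].x_start / bw))
                       for i in range(self.grid.n_rows)]

            def ev(sym):
                return sym.const + sum(v[c] * w for c, w in sym.terms)

            for (bank, g), col in self._carr_u.items():
                fn = self._sym["l_out" if bank == "left" else "r_out"]
                vals = [ev(fn(n, g - row_off[n]))
                        for n in self._carr_rows[bank]]
                v[col] = min(max(vals) + 0.05, T0)
        if self.n_aux:
            core = v.copy()
            for (i, k, c, bank, s_col) in self._tng_aux:
                expr = self._tng_expr(i, k, c, bank)
                val = expr.const + sum(core[col] * coef
                                       for col, coef in expr.terms)
                v[s_col] = abs(val) + 0.1
        return v

    # ------------------------------------------------------------------
    def fit(self, options: SolverOptions | None = None) -> "LeafTrajectoryResults":
        """Solve the program to global optimality and decode the solution."""
        opts = options or SolverOptions()
        qp = solve_qp(self.P_sparse, self.q, self.A, self.b,
                      P_op=self.P_op, x0=self.initial_point(), options=opts,
                      precond_rows=self._precond_rows)
        return LeafTrajectoryResults(self, qp)

    # decode -----------------------------------------------------------
    def decode(self, v: np.ndarray) -> TrajectorySolution:
        T = float(v[self.T_col])
        rows = []
        for i in range(self.grid.n_rows):
            L = self._layout[i]
            a, e, J, off = L["a"], L["e"], L["J"], L["off"]
            x = self.grid.boundaries(i)
            r_out = np.zeros(J + 1)
            r_in = np.zeros(J + 1)
            l_out = np.full(J + 1, T)
            l_in = np.full(J + 1, T)
            r_out[a:J] = v[off:off + L["nro"]]
            r_out[J] = T
            r_in[a + 1:J + 1] = v[off + L["nro"]:off + L["nro"] + L["nri"]]
            l_out[:e] = v[off + L["nro"] + L["nri"]:
                          off + L["nro"] + L["nri"] + L["nlo"]]
            l_in[0] = 0.0
            l_in[1:e + 1] = v[off + L["nro"] + L["nri"] + L["nlo"]:
                              off + L["nro"] + L["nri"] + L["nlo"] + L["nli"]]
            rows.append(RowTrajectory(x=x, r_in=r_in, r_out=r_out,
                                      l_in=l_in, l_out=l_out,
                                      lead_start=a, trail_end=e))
        return TrajectorySolution(rows=rows, t_total=T, grid=self.grid,
                                  machine=self.machine)


class LeafTrajectoryResults:
    """Fitted trajectories with diagnostics, dose and deliverability checks."""

    def __init__(self, model: LeafTrajectoryModel, qp: QPSolution):
        self.model = model
        self.qp = qp
        self.solution = model.decode(qp.x)
        self.converged = qp.converged
        self.iterations = qp.iterations

    # --- derived quantities -------------------------------------------
    def fluence(self) -> FluenceTimeMap:
        return effective_time(self.solution)

    def tng(self) -> TnGMap:
        return tng_times(self.solution)

    @property
    def t_total(self) -> float:
        return self.solution.t_total

    @property
    def mu_total(self) -> float:
        return self.t_total * self.model.machine.dose_rate_mod_per_s

    def dose(self, normalized: bool = False) -> DoseMap:
        dm = self.model.influence.dose(self.fluence().x)
        return dm.normalized() if normalized else dm

    def objective_breakdown(self) -> dict:
        w = self.model.weights
        d = self.dose().values
        resid = d - self.model._target_plane
        dose_term = w.lambda1 * float((resid ** 2).sum())
        time_term = w.lambda2 * self.t_total
        tng_term = w.lambda3 * self.tng().total
        return {"dose": dose_term, "time": time_term, "tng": tng_term,
                "total": dose_term + time_term + tng_term}

    def validate(self, tol_time: float = 1e-5,
                 tol_space: float = 1e-4) -> ConstraintReport:
        return validate_solution(self.solution, self.model.machine,
                                 self.model.grid, tol_time, tol_space)

    def control_points(self, n_points: int = 50):
        from .delivery import sample_control_points
        return sample_control_points(self.solution, self.model.machine, n_points)

    # --- plotting ------------------------------------------------------
    def plot_trajectories(self, rows=None, ax=None):
        from .plotting import plot_trajectories
        return plot_trajectories(self.solution, rows=rows, ax=ax)

    def plot_fluence(self, ax=None):
        from .plotting import plot_fluence
        return plot_fluence(self.fluence(), ax=ax)

    def plot_profiles(self, axis: str = "crossline", ax=None):
        from .plotting import plot_profiles
        from .pipeline import reference_scaled
        return plot_profiles(self.dose(), reference_scaled(self.model),
                             axis=axis, ax=ax)

    # --- reporting -----------------------------------------------------
    def summary(self) -> str:
        m = self.model
        terms = self.objective_breakdown()
        rep = self.validate()
        lines = [
            "Leaf Trajectory Optimization Results",
            "=" * 52,
            f"{'field':<28}{m.grid.name or 'custom'}",
            f"{'active rows':<28}{m.grid.n_rows}",
            f"{'variables / constraints':<28}{m.n_variables} / {m.A.shape[0]}",
            f"{'solver status':<28}{self.qp.status} "
            f"({self.qp.iterations} iterations, {self.qp.wall_time:.1f} s)",
            f"{'weights l1/l2/l3':<28}{m.weights.lambda1:g} / "
            f"{m.weights.lambda2:g} / {m.weights.lambda3:g}",
            f"{'beam-on time T':<28}{self.t_total:.3f} s",
            f"{'total MU':<28}{self.mu_total:.1f}",
            f"{'objective (dose/time/T&G)':<28}{terms['dose']:.4g} / "
            f"{terms['time']:.4g} / {terms['tng']:.4g}",
            f"{'deliverable':<28}{'yes' if rep.passed else 'NO'}",
            "",
            rep.summary(),
        ]
        return "\n".join(lines)


def build_model(grid: FieldGrid, influence: DoseInfluence, reference: DoseMap,
                machine: MachineSpec | None = None,
                weights: Weights | None = None,
                prescription_mu: float = 35.0) -> LeafTrajectoryModel:
    """Functional alias for :class:`LeafTrajectoryModel`."""
    return LeafTrajectoryModel(grid, influence, reference, weights=weights,
                               machine=machine, prescription_mu=prescription_mu)


def solve(model: LeafTrajectoryModel,
          options: SolverOptions | None = None) -> LeafTrajectoryResults:
    """Solve a built model (global optimum; the program is convex)."""
    return model.fit(options)
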