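"""Convex quadratic programming by a primal-dual interior-point method.

Solves

    minimize    0.5 x' P x + q' x
    subject to  A x <= b

with P positive semidefinite, using Mehrotra's predictor-corrector
path-following scheme. The Newton systems

    (P + A' W A + delta I) dx = rhs,   W = diag(z / s)

are solved either directly (sparse LDL via SuperLU) when an exact sparse
P is available, or by preconditioned conjugate gradients when P is given
as an abstract operator, with the preconditioner built from a sparse
approximation of P plus the exact (and increasingly dominant) constraint
term A' W A.

The objective is internally rescaled so dual quantities are O(1); the
reported multipliers are on the original scale. The method is
deterministic: no randomness anywhere.
"""
from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, splu


@dataclass
class SolverOptions:
    """Interior-point settings.

    ``tol_feas``/``tol_dual``/``tol_gap`` are relative convergence
    tolerances on the primal residual, dual residual and complementarity
    gap. ``reg`` is a static primal regularization added to the Newton
    matrix. ``cg_tol_floor`` bounds how tight the inner PCG solves get.
    """

    max_iter: int = 100
    tol_feas: float = 1e-9
    tol_dual: float = 1e-6
    tol_gap: float = 1e-8
    step_frac: float = 0.995
    reg: float = 1e-10
    cg_max: int = 400
    cg_tol_floor: float = 1e-9
    verbose: bool = False


@dataclass
class QPSolution:
    x: np.ndarray
    z: np.ndarray
    s: np.ndarray
    status: str
    iterations: int
    objective: float
    mu: float
    primal_residual: float
    dual_residual: float
    cg_iterations: int = 0
    wall_time: float = 0.0

    @property
    def converged(self) -> bool:
        return self.status == "optimal"


class QPSolverError(RuntimeError):
    """Raised when the interior point method fails to converge."""

    def __init__(self, message: str, solution: "QPSolution | None" = None):
        super().__init__(message)
        self.solution = solution


def _max_step(u: np.ndarray, du: np.ndarray) -> float:
    neg = du < 0
    if not np.any(neg):
        return np.inf
    return float(np.min(-u[neg] / du[neg]))


def solve_qp(P, q, A, b, *, P_op=None, x0=None,
             options: SolverOptions | None = None,
             precond_rows=None) -> QPSolution:
    """Solve the inequality-constrained QP.

    Parameters
    ----------
    P : scipy sparse matrix
        Either the exact Hessian (when ``P_op`` is None) or a sparse
        approximation used only inside the preconditioner.
    q, b : ndarray
        Linear objective term and constraint right-hand side.
    A : scipy sparse matrix
        Inequality matrix, ``A x <= b``.
    P_op : callable, optional
        Exact Hessian apply ``v -> P v``; switches the Newton solves to
        preconditioned CG.
    x0 : ndarray, optional
        Warm-start point; need not be feasible.
    precond_rows : ndarray of bool, optional
        Constraint rows whose barrier term enters the *preconditioner*
        (all rows always enter the exact Newton operator). Dropping
        far-from-active rows that would cause heavy factorization
        fill-in — e.g. constraints coupling every leaf row — keeps the
        factors sparse at no accuracy cost.
    """
    t_start = time.perf_counter()
    opts = options or SolverOptions()
    A = sparse.csr_matrix(A)
    m, n = A.shape
    q = np.asarray(q, dtype=float)
    b = np.asarray(b, dtype=float)
    P = sparse.csr_matrix(P)

    # objective rescaling: keeps duals O(1) regardless of weight magnitudes
    obj_scale = max(1.0, float(np.abs(q).max()))
    qs = q / obj_scale
    Ps = P / obj_scale
    if P_op is None:
        P_apply = lambda v: Ps @ v
    else:
        P_apply = lambda v: P_op(v) / obj_scale

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    s = b - A @ x
    s = np.maximum(s, 0.1)
    z = np.ones(m)

    b_scale = 1.0 + float(np.abs(b).max())
    q_scale = 1.0 + float(np.abs(qs).max())
    cg_total = 0
    mu0 = None
    status = "max_iter"
    AT = A.T.tocsr()

    for it in range(opts.max_iter):
        Px = P_apply(x)
        r_d = Px + qs + AT @ z
        r_p = A @ x + s - b
        mu = float(s @ z) / m
        if mu0 is None:
            mu0 = mu
        pri = float(np.abs(r_p).max())
        dua = float(np.abs(r_d).max())
        obj = float(0.5 * x @ Px + qs @ x)
        if opts.verbose:
            print(f"  ip iter {it:3d}: mu={mu:9.2e} pri={pri:9.2e} "
                  f"dua={dua:9.2e} obj={obj * obj_scale:.6e}")
        d_scale = q_scale + float(np.abs(Px).max())
        gap_ok = mu <= opts.tol_gap * max(1.0, abs(obj))
        # primary test: feasibility + dual residual + gap; the fallback
        # accepts a tiny gap with a merely-small dual residual (inexact
        # Newton steps can stall the dual a little above tol_dual), but
        # never a genuinely unconverged dual
        if (pri <= opts.tol_feas * b_scale
                and (dua <= opts.tol_dual * d_scale and gap_ok
                     or (dua <= 1e3 * opts.tol_dual * d_scale
                         and mu <= 1e-2 * opts.tol_gap * max(1.0, abs(obj))))):
            status = "optimal"
            break

        W = np.clip(z / s, 1e-14, 1e14)
        if precond_rows is None or P_op is None:
            WA = sparse.diags(W) @ A
            AWA = AT @ WA
        else:
            Ap = A[precond_rows]
            AWA = Ap.T @ (sparse.diags(W[precond_rows]) @ Ap)
        lu = None
        reg = opts.reg
        for _ in range(4):
            K_sparse = (Ps + AWA
                        + sparse.identity(n, format="csr") * reg).tocsc()
            try:
                lu = splu(K_sparse)
                break
            except RuntimeError:
                reg = max(reg, 1e-12) * 1e3
        if lu is None:
            raise QPSolverError("Newton matrix factorization failed")
        if P_op is None:
            solve_K = lu.solve
        else:
            K_lin = LinearOperator(
                (n, n), matvec=lambda v: P_apply(v) + AT @ (W * (A @ v))
                + opts.reg * v)
            M_pre = LinearOperator((n, n), matvec=lu.solve)
            mu_rel = mu / max(mu0, 1e-300)
            cg_tol = max(opts.cg_tol_floor,
                         min(1e-3, 0.05 * np.sqrt(mu_rel)))

            def solve_K(rhs):
                nonlocal cg_total
                count = [0]

                def cb(_):
                    count[0] += 1

                sol, info = cg(K_lin, rhs, M=M_pre, rtol=cg_tol,
                               atol=0.0, maxiter=opts.cg_max, callback=cb)
                cg_total += count[0]
                # info > 0 means maxiter hit: accept the iterate, the
                # interior point method tolerates inexact steps
                return sol

        # predictor (affine scaling) step
        rhs_aff = -(Px + qs) - AT @ (W * r_p)
        dx_aff = solve_K(rhs_aff)
        ds_aff = -r_p - A @ dx_aff
        dz_aff = -z - W * ds_aff
        a_p_aff = min(1.0, _max_step(s, ds_aff))
        a_d_aff = min(1.0, _max_step(z, dz_aff))
        mu_aff = float((s + a_p_aff * ds_aff) @ (z + a_d_aff * dz_aff)) / m
        sigma = float(np.clip((mu_aff / mu) ** 3, 1e-8, 1.0))

        # corrector step
        comp = (sigma * mu - ds_aff * dz_aff) / s
        rhs = rhs_aff - AT @ comp
        dx = solve_K(rhs)
        ds = -r_p - A @ dx
        dz = comp - z - W * ds

        a_p = min(1.0, opts.step_frac * _max_step(s, ds))
        a_d = min(1.0, opts.step_frac * _max_step(z, dz))
        x += a_p * dx
        s += a_p * ds
        z += a_d * dz

    Px = P_apply(x)
    sol = QPSolution(
        x=x, z=z * obj_scale, s=s, status=status, iterations=it + 1,
        objective=float(0.5 * x @ (P_apply(x)) + qs @ x) * obj_scale,
        mu=float(s @ z) / m,
        primal_residual=float(np.abs(A @ x + s - b).max()),
        dual_residual=float(np.abs(Px + qs + AT @ z).max()) * obj_scale,
        cg_iterations=cg_total,
        wall_time=time.perf_counter() - t_start,
    )
    if status != "optimal":
        raise QPSolverError(
            f"interior point did not converge in {opts.max_iter} iterations "
            f"(mu={sol.mu:.2e}, primal residual={sol.primal_residual:.2e})",
            solution=sol)
    return sol
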