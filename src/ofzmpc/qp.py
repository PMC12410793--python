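"""Dense convex quadratic programming.

Solves

    minimize    0.5 x' H x + g' x
    subject to  A x  = b
                G x <= h

with H symmetric positive (semi)definite, via a Mehrotra
predictor-corrector primal-dual interior-point method.  Problems here are
small (tens of variables), so all linear algebra is dense.  The solver is
deliberately self-contained: the controller must never inject insulin on
the back of a half-converged answer, so failures are reported through
``status`` rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["QPResult", "solve_qp"]

_STATUS_OPTIMAL = "optimal"
_STATUS_MAXITER = "max_iterations"
_STATUS_NUMERICAL = "numerical_failure"


@dataclass
class QPResult:
    x: np.ndarray
    fun: float
    status: str
    iterations: int
    eq_residual: float
    ineq_violation: float
    duals_eq: np.ndarray = field(default=None, repr=False)
    duals_ineq: np.ndarray = field(default=None, repr=False)

    @property
    def success(self) -> bool:
        return self.status == _STATUS_OPTIMAL


def _objective(H, g, x) -> float:
    return float(0.5 * x @ H @ x + g @ x)


def solve_qp(
    H,
    g,
    A=None,
    b=None,
    G=None,
    h=None,
    *,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> QPResult:
    """Solve the convex QP; see module docstring for the problem form."""
    H = np.asarray(H, dtype=float)
    g = np.asarray(g, dtype=float).reshape(-1)
    n = g.size
    if H.shape != (n, n):
        raise ValueError(f"H must be {n}x{n}, got {H.shape}")
    H = 0.5 * (H + H.T)

    if A is None or len(np.atleast_1d(A)) == 0:
        A = np.zeros((0, n))
        b = np.zeros(0)
    else:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        b = np.asarray(b, dtype=float).reshape(-1)
    if G is None or len(np.atleast_1d(G)) == 0:
        G = np.zeros((0, n))
        h = np.zeros(0)
    else:
        G = np.atleast_2d(np.asarray(G, dtype=float))
        h = np.asarray(h, dtype=float).reshape(-1)
    meq, mineq = A.shape[0], G.shape[0]

    if mineq == 0:
        return _solve_eqp(H, g, A, b)

    H0, g0, G0, h0 = H, g, G, h

    # Jacobi equilibration: the controller's condensed cost mixes dose,
    # state and slack columns spanning ~14 orders of magnitude; symmetric
    # diagonal scaling keeps the KKT solves accurate.
    hd = np.abs(np.diag(H))
    tau = 1e-10 * max(hd.max(initial=0.0), 1.0)
    col = 1.0 / np.sqrt(np.maximum(hd, tau))
    H = H * col[None, :] * col[:, None]
    g = g * col
    A = A * col[None, :]
    G = G * col[None, :]
    if meq:
        row = np.linalg.norm(A, axis=1)
        row = np.where(row > 0, row, 1.0)
        A = A / row[:, None]
        b = b / row

    # Starting point: equality-constrained solution, slacks/duals pushed
    # safely interior.
    x = _solve_eqp(H, g, A, b).x
    if not np.all(np.isfinite(x)):
        x = np.zeros(n)
    s = h - G @ x
    shift = max(1.0, -1.5 * s.min()) if s.min() <= 0 else max(1.0, 0.1 * s.mean())
    s = np.maximum(s + shift, 1.0)
    z = np.ones(mineq)
    y = np.zeros(meq)

    scale = 1.0 + max(
        np.abs(g).max(initial=0.0),
        np.abs(b).max(initial=0.0),
        np.abs(h).max(initial=0.0),
    )

    status = _STATUS_MAXITER
    it = 0
    for it in range(1, max_iter + 1):
        rd = H @ x + g + A.T @ y + G.T @ z
        rb = A @ x - b
        rh = G @ x + s - h
        mu = z @ s / mineq

        if (
            max(np.abs(rd).max(), np.abs(rb).max(initial=0.0), np.abs(rh).max())
            < tol * scale
            and mu < tol * scale
        ):
            status = _STATUS_OPTIMAL
            break

        W = z / s  # diagonal of the G' diag(z/s) G term
        K = H + (G.T * W) @ G

        # --- affine (predictor) direction: sigma = 0 ---
        rs = z * s
        rhs_x = -rd - G.T @ ((z * rh - rs) / s)
        dx_aff, dy_aff, ok = _kkt_solve(K, A, rhs_x, -rb)
        if not ok:
            status = _STATUS_NUMERICAL
            break
        ds_aff = -rh - G @ dx_aff
        dz_aff = -(rs + z * ds_aff) / s

        alpha_aff = _step_length(s, ds_aff, z, dz_aff)
        mu_aff = (z + alpha_aff * dz_aff) @ (s + alpha_aff * ds_aff) / mineq
        sigma = (max(mu_aff, 0.0) / mu) ** 3 if mu > 0 else 0.0

        # --- corrector direction ---
        rs = z * s + dz_aff * ds_aff - sigma * mu
        rhs_x = -rd - G.T @ ((z * rh - rs) / s)
        dx, dy, ok = _kkt_solve(K, A, rhs_x, -rb)
        if not ok:
            status = _STATUS_NUMERICAL
            break
        ds = -rh - G @ dx
        dz = -(rs + z * ds) / s

        alpha = 0.99 * _step_length(s, ds, z, dz)
        x = x + alpha * dx
        s = s + alpha * ds
        z = z + alpha * dz
        if meq:
            y = y + alpha * dy

    x_orig = x * col
    return QPResult(
        x=x_orig,
        fun=_objective(H0, g0, x_orig),
        status=status,
        iterations=it,
        eq_residual=float(np.abs(A @ x - b).max(initial=0.0)),
        ineq_violation=float(np.maximum(G0 @ x_orig - h0, 0.0).max(initial=0.0)),
        duals_eq=y,
        duals_ineq=z,
    )


def _step_length(s, ds, z, dz) -> float:
    alpha = 1.0
    neg = ds < 0
    if neg.any():
        alpha = min(alpha, np.min(-s[neg] / ds[neg]))
    neg = dz < 0
    if neg.any():
        alpha = min(alpha, np.min(-z[neg] / dz[neg]))
    return float(alpha)


def _kkt_solve(K, A, rhs_x, rhs_y):
    """Solve the symmetric KKT system [[K, A'], [A, 0]] [dx, dy] = rhs."""
    n = K.shape[0]
    meq = A.shape[0]
    if meq == 0:
        try:
            dx = np.linalg.solve(K + 1e-12 * np.eye(n), rhs_x)
        except np.linalg.LinAlgError:
            return None, None, False
        return dx, np.zeros(0), np.all(np.isfinite(dx))
    M = np.zeros((n + meq, n + meq))
    M[:n, :n] = K
    M[:n, n:] = A.T
    M[n:, :n] = A
    M[:n, :n] += 1e-12 * np.eye(n)
    M[n:, n:] -= 1e-12 * np.eye(meq)
    rhs = np.concatenate([rhs_x, rhs_y])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        try:
            sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
        except np.linalg.LinAlgError:
            return None, None, False
    dx, dy = sol[:n], sol[n:]
    return dx, dy, bool(np.all(np.isfinite(sol)))


def _solve_eqp(H, g, A, b) -> QPResult:
    """Equality-constrained QP via one KKT solve (used standalone and as
    the interior-point warm start)."""
    n = g.size
    meq = A.shape[0]
    reg = 1e-10 * (1.0 + np.abs(np.diag(H)).max(initial=0.0))
    K = H + reg * np.eye(n)
    dx, dy, ok = _kkt_solve(K, A, -g, b)
    status = _STATUS_OPTIMAL if ok else _STATUS_NUMERICAL
    x = dx if dx is not None else np.zeros(n)
    return QPResult(
        x=x,
        fun=_objective(H, g, x),
        status=status,
        iterations=1,
        eq_residual=float(np.abs(A @ x - b).max(initial=0.0)),
        ineq_violation=0.0,
        duals_eq=dy if dy is not None else np.zeros(meq),
        duals_ineq=np.zeros(0),
    )
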