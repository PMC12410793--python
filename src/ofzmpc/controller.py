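"""Offset-free zone MPC over the impulsive glucose model.

Each period the controller solves, over the bolus sequence and an
artificial equilibrium ``(xa, ua)``,

    min  sum_j ||x(j) - xa||_Q^2 + sum_j ||u(j) - ua||_R^2 + Vf(xa, ua)
    s.t. x(0) = xhat(k),  d held constant over the horizon,
         x(j+1) = Ad x(j) + Bud u(j) + Bdd d + Ed,
         u(j) in [u_min, u_max],
         x(Hp) = xa,
         xa = Ad xa + Bud ua + Bdd d + Ed,
         ya = C xa + Cd d,

and applies the first bolus.  The target-equilibrium set is realized
implicitly by the equilibrium equalities together with ``ya`` membership
of the glycemic zone; the terminal cost ``Vf`` is ``P`` times the
output-space distance of ``ya`` to the zone plus the distance of ``ua``
to the input box, encoded exactly in the QP through L1 zone slack (the
equilibrium equalities and the input box stay hard).  Boluses beyond the
control horizon ``Hu`` are pinned to ``ua``.  Meals are never announced:
the prediction always carries ``r = 0``.

All decision inputs are per-period boluses in U, entering the sampled
dynamics as impulses through ``Bud``.  A small strictly convex
regularization (ridge on all decision variables plus a gentle pull of the
equilibrium output toward the zone centre) makes the optimum unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import qp as qpmod
from .core_model import NX, ImpulsiveModel, StateVector
from .observer import AugmentedModel, KalmanEstimator

__all__ = [
    "ZoneSpec",
    "ControllerConfig",
    "ControlSolution",
    "ZoneMPC",
    "dynamic_cost",
    "terminal_cost",
    "target_input_interval",
    "closed_loop_step",
]


@dataclass(frozen=True)
class ZoneSpec:
    """Glycemic target zone and bolus limits."""

    y_lo: float = 90.0
    y_hi: float = 130.0
    u_min: float = 0.0
    u_max: float = 1.0
    x_bounds: tuple | None = None  # optional ((lo, hi) per state) box

    def __post_init__(self) -> None:
        if not self.y_lo < self.y_hi:
            raise ValueError(f"zone requires y_lo < y_hi, got [{self.y_lo}, {self.y_hi}]")
        if not 0.0 <= self.u_min < self.u_max:
            raise ValueError(
                f"bolus bounds require 0 <= u_min < u_max, got [{self.u_min}, {self.u_max}]"
            )


def _default_Q() -> np.ndarray:
    Q = np.zeros((NX, NX))
    Q[0, 0] = 1.0  # penalize glycemia deviation only
    return Q


@dataclass(frozen=True)
class ControllerConfig:
    """Horizons, weights and period.

    The in-vivo tuning fixed Hp = 100 and Hu = 30 at a 5-minute period;
    the numeric weights were never reported, so the defaults here are the
    package's own (logged with every run).
    """

    Hp: int = 100
    Hu: int = 30
    T: float = 5.0
    Q: np.ndarray = field(default_factory=_default_Q)
    R: float = 10.0
    P: float = 1e4
    ridge: float = 1e-7
    center_weight: float = 5.0  # pull of ya toward the zone centre (uniqueness + interior settling)
    dose_step: float | None = None  # optional pump quantization (U)

    def __post_init__(self) -> None:
        if not (0 < self.Hu <= self.Hp):
            raise ValueError(f"need 0 < Hu <= Hp, got Hu={self.Hu}, Hp={self.Hp}")
        if self.T <= 0:
            raise ValueError(f"period T must be positive, got {self.T}")
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (NX, NX) or np.any(np.linalg.eigvalsh(0.5 * (Q + Q.T)) < -1e-12):
            raise ValueError("Q must be a 5x5 positive semidefinite matrix")
        if self.R <= 0 or self.P <= 0:
            raise ValueError("R and P must be positive")
        object.__setattr__(self, "Q", 0.5 * (Q + Q.T))


@dataclass(frozen=True)
class ControlSolution:
    """Optimal bolus plan for one period."""

    u_seq: np.ndarray          # (Hp,) planned boluses, tail pinned to ua
    xa: np.ndarray             # (5,) artificial equilibrium state
    ua: float                  # equilibrium bolus (U)
    ya: float                  # equilibrium output (mg/dL)
    cost: float                # V_N at the optimum
    status: str                # "optimal" | "zone_relaxed" | "failed-safe"
    applied: float             # first bolus, the one sent to the pump
    slack: tuple[float, float] = (0.0, 0.0)


def dynamic_cost(traj, u_seq, xa, ua, Q, R) -> float:
    """Stage cost: weighted squared deviations of states and boluses from
    the artificial equilibrium, summed over the horizon."""
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    u_seq = np.asarray(u_seq, dtype=float).reshape(-1)
    if traj.shape[0] != u_seq.size:
        raise ValueError(
            f"trajectory ({traj.shape[0]}) and input sequence ({u_seq.size}) "
            "must cover the same horizon"
        )
    xa = np.asarray(xa, dtype=float).reshape(-1)
    dx = traj - xa
    du = u_seq - float(ua)
    return float(np.einsum("ji,ik,jk->", dx, np.asarray(Q, dtype=float), dx) + float(R) * du @ du)


def _interval_distance(v: float, lo: float, hi: float) -> float:
    return max(0.0, lo - v, v - hi)


def target_input_interval(
    aug: AugmentedModel, zone: ZoneSpec, dhat
) -> tuple[float, float] | None:
    """Bolus interval whose equilibria put the output inside the zone.

    Equilibria are affine in the bolus: ``x_eq(u) = (I - Ad)^{-1} (Bud u
    + Bdd d + Ed)`` and ``ya(u) = C x_eq(u) + Cd d``.  Returns the
    intersection of the zone preimage with ``[u_min, u_max]``, or None if
    it is empty (degenerate zone for the current disturbance estimate).
    """
    imp = aug.imp
    dhat = np.atleast_1d(np.asarray(dhat, dtype=float))
    I_A = np.eye(NX) - imp.Ad
    w = aug.Bdd @ dhat + imp.Ed
    B = imp.Bud
    x0 = np.linalg.solve(I_A, w)
    x1 = np.linalg.solve(I_A, B)
    cd = float(aug.Ct[0, NX:] @ dhat)
    alpha = float(x0[0]) + cd       # ya at u = 0
    beta = float(x1[0])             # d ya / d u  (negative: insulin lowers glucose)
    if abs(beta) < 1e-14:
        if zone.y_lo <= alpha <= zone.y_hi:
            return (zone.u_min, zone.u_max)
        return None
    u_at = sorted(((zone.y_lo - alpha) / beta, (zone.y_hi - alpha) / beta))
    lo = max(zone.u_min, u_at[0])
    hi = min(zone.u_max, u_at[1])
    if lo > hi:
        return None
    return (lo, hi)


def terminal_cost(xa, ua, zone: ZoneSpec, dhat, aug: AugmentedModel, P: float) -> float:
    """``P`` times the surrogate distance of the artificial pair to the
    target-equilibrium set: output-space distance of ``ya = C xa + Cd d``
    to the zone, plus the distance of ``ua`` to the bolus box.  Zero iff
    the pair is a target equilibrium (given the equilibrium equalities,
    which the QP enforces exactly)."""
    xa = np.asarray(xa, dtype=float).reshape(-1)
    dhat = np.atleast_1d(np.asarray(dhat, dtype=float))
    ya = float(aug.Ct[0, :NX] @ xa + aug.Ct[0, NX:] @ dhat)
    dist_y = _interval_distance(ya, zone.y_lo, zone.y_hi)
    dist_u = _interval_distance(float(ua), zone.u_min, zone.u_max)
    return float(P) * (dist_y + dist_u)


@dataclass
class QPInstance:
    """Assembled QP with the decision-variable layout
    ``[u_0..u_{Hu-1}, xa (5), ua, s_lo, s_hi]``."""

    H: np.ndarray
    g: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    G_in: np.ndarray
    h_in: np.ndarray
    Hu: int
    Hp: int
    idx_xa: slice
    idx_ua: int
    idx_slack: slice


class ZoneMPC:
    """Receding-horizon offset-free zone controller.

    Prediction matrices depend only on the model and configuration, so
    they are built once; per-period work is assembling the affine terms
    from ``(xhat, dhat)`` and one small QP solve.
    """

    def __init__(self, aug: AugmentedModel, zone: ZoneSpec, cfg: ControllerConfig):
        if abs(aug.imp.T - cfg.T) > 1e-9:
            raise ValueError(
                f"model period {aug.imp.T} and controller period {cfg.T} differ"
            )
        self.aug = aug
        self.zone = zone
        self.cfg = cfg
        self._precompute()

    # -- horizon condensation ------------------------------------------
    def _precompute(self) -> None:
        aug, cfg = self.aug, self.cfg
        imp = aug.imp
        Hp, Hu = cfg.Hp, cfg.Hu
        n = Hu + NX + 1 + 2
        self.n_var = n
        self.idx_xa = slice(Hu, Hu + NX)
        self.idx_ua = Hu + NX
        self.idx_slack = slice(Hu + NX + 1, Hu + NX + 3)

        B = imp.Bud  # per-bolus (U) input map: impulse at the sampling instant

        # Powers of Ad and their partial sums.
        Phi = np.empty((Hp + 1, NX, NX))
        Phi[0] = np.eye(NX)
        for j in range(Hp):
            Phi[j + 1] = imp.Ad @ Phi[j]
        Cum = np.empty((Hp + 1, NX, NX))
        Cum[0] = 0.0
        for j in range(Hp):
            Cum[j + 1] = Cum[j] + Phi[j]
        self._Phi, self._Cum = Phi, Cum

        # x(j) = M[j] z + Phi[j] xhat + Cum[j] w,  w = Bdd d + Ed.
        M = np.zeros((Hp + 1, NX, n))
        for j in range(Hp):
            M[j + 1] = imp.Ad @ M[j]
            col = j if j < Hu else self.idx_ua
            M[j + 1][:, col] += B
        self._M = M

        Xa = np.zeros((NX, n))
        Xa[:, self.idx_xa] = np.eye(NX)

        # Quadratic stage cost, condensed.
        Q = cfg.Q
        Hq = np.zeros((n, n))
        G1 = np.zeros((n, NX))  # multiplies xhat in the linear term
        G2 = np.zeros((n, NX))  # multiplies w in the linear term
        for j in range(Hp):
            Rm = M[j] - Xa
            QR = Q @ Rm
            Hq += Rm.T @ QR
            G1 += Rm.T @ (Q @ Phi[j])
            G2 += Rm.T @ (Q @ Cum[j])
        Hq *= 2.0
        self._G1 = 2.0 * G1
        self._G2 = 2.0 * G2

        for j in range(Hu):
            row = np.zeros(n)
            row[j] = 1.0
            row[self.idx_ua] = -1.0
            Hq += 2.0 * cfg.R * np.outer(row, row)

        Hq += 2.0 * cfg.ridge * np.eye(n)

        # Tie-break: gentle quadratic pull of the equilibrium output toward
        # the zone centre, so the in-zone optimum is unique and away from
        # the hypoglycemic edge.
        row_ya = np.zeros(n)
        row_ya[self.idx_xa] = aug.Ct[0, :NX]
        Hq += 2.0 * cfg.center_weight * np.outer(row_ya, row_ya)
        self._row_ya = row_ya
        self._H = Hq

        # Equality blocks (RHS filled per solve).  The terminal condition
        # x(Hp) = xa is imposed in the equivalent form x(Hu) = xa: inputs
        # beyond Hu are pinned to ua and xa is constrained to be an
        # equilibrium, so (Ad invertible) x(Hp) - xa = Ad^(Hp-Hu) (x(Hu) -
        # xa) vanishes iff x(Hu) = xa.  The direct x(Hp) rows are nearly
        # parallel to the equilibrium rows (Ad^(Hp-Hu) is tiny) and give
        # the KKT system enormous multipliers.
        self._j_term = Hu
        A_term = M[self._j_term] - Xa
        A_eq2 = np.zeros((NX, n))                  # (I - Ad) xa - B ua = w
        A_eq2[:, self.idx_xa] = np.eye(NX) - imp.Ad
        A_eq2[:, self.idx_ua] = -B
        self._A_eq = np.vstack([A_term, A_eq2])

        # Inequalities: zone (slacked), bolus boxes, slack positivity.
        rows, rhs_template = [], []
        cvec = aug.Ct[0, :NX]
        r_hi = np.zeros(n)
        r_hi[self.idx_xa] = cvec
        r_hi[Hu + NX + 2] = -1.0  # - s_hi
        rows.append(r_hi); rhs_template.append(("y_hi", None))
        r_lo = np.zeros(n)
        r_lo[self.idx_xa] = -cvec
        r_lo[Hu + NX + 1] = -1.0  # - s_lo
        rows.append(r_lo); rhs_template.append(("y_lo", None))
        for j in list(range(Hu)) + [self.idx_ua]:
            up = np.zeros(n); up[j] = 1.0
            dn = np.zeros(n); dn[j] = -1.0
            rows.append(up); rhs_template.append(("u_max", None))
            rows.append(dn); rhs_template.append(("u_min", None))
        for k in (Hu + NX + 1, Hu + NX + 2):
            r = np.zeros(n); r[k] = -1.0
            rows.append(r); rhs_template.append(("slack", None))
        self._G_in = np.vstack(rows)
        self._rhs_kind = [k for k, _ in rhs_template]

        # Optional per-state box on the predicted trajectory.
        self._state_rows = None
        if self.zone.x_bounds is not None:
            srows, skind = [], []
            for i, (lo, hi) in enumerate(self.zone.x_bounds):
                for j in range(1, Hp + 1):
                    if hi is not None and np.isfinite(hi):
                        srows.append((M[j][i], j, i, +1.0, float(hi)))
                    if lo is not None and np.isfinite(lo):
                        srows.append((-M[j][i], j, i, -1.0, float(lo)))
            self._state_rows = srows

    # -- per-period assembly -------------------------------------------
    def build_qp(self, xhat: StateVector, dhat) -> QPInstance:
        aug, cfg, zone = self.aug, self.cfg, self.zone
        imp = aug.imp
        xhat = np.asarray(xhat, dtype=float).reshape(NX)
        dhat = np.atleast_1d(np.asarray(dhat, dtype=float))
        w = aug.Bdd @ dhat + imp.Ed
        cd = float(aug.Ct[0, NX:] @ dhat)

        g = self._G1 @ xhat + self._G2 @ w
        g[self.idx_slack] += cfg.P  # L1 penalty on zone violation
        y_center = 0.5 * (zone.y_lo + zone.y_hi)
        g += 2.0 * cfg.center_weight * (cd - y_center) * self._row_ya

        jt = self._j_term
        b_eq = np.concatenate([-(self._Phi[jt] @ xhat + self._Cum[jt] @ w), w])

        h = np.empty(self._G_in.shape[0])
        for i, kind in enumerate(self._rhs_kind):
            if kind == "y_hi":
                h[i] = zone.y_hi - cd
            elif kind == "y_lo":
                h[i] = -zone.y_lo + cd
            elif kind == "u_max":
                h[i] = zone.u_max
            elif kind == "u_min":
                h[i] = -zone.u_min
            else:
                h[i] = 0.0
        G = self._G_in
        if self._state_rows:
            extra_rows = []
            extra_rhs = []
            for row, j, i, sign, bound in self._state_rows:
                extra_rows.append(row)
                c_ji = float(self._Phi[j][i] @ xhat + self._Cum[j][i] @ w)
                extra_rhs.append(sign * bound - sign * c_ji)
            G = np.vstack([G, np.array(extra_rows)])
            h = np.concatenate([h, np.array(extra_rhs)])

        return QPInstance(
            H=self._H,
            g=g,
            A_eq=self._A_eq,
            b_eq=b_eq,
            G_in=G,
            h_in=h,
            Hu=cfg.Hu,
            Hp=cfg.Hp,
            idx_xa=self.idx_xa,
            idx_ua=self.idx_ua,
            idx_slack=self.idx_slack,
        )

    def solve(self, qp: QPInstance, xhat, dhat) -> ControlSolution:
        cfg, zone, aug = self.cfg, self.zone, self.aug
        res = qpmod.solve_qp(qp.H, qp.g, qp.A_eq, qp.b_eq, qp.G_in, qp.h_in, max_iter=100)
        # A stalled interior-point run whose iterate is feasible to well
        # below dosing precision is still a safe, usable plan.
        usable = res.success or (
            res.eq_residual < 1e-4 and res.ineq_violation < 1e-6
        )
        if not usable:
            return ControlSolution(
                u_seq=np.zeros(cfg.Hp),
                xa=np.full(NX, np.nan),
                ua=0.0,
                ya=float("nan"),
                cost=float("nan"),
                status="failed-safe",
                applied=0.0,
            )
        z = res.x
        ua = float(z[qp.idx_ua])
        xa = np.array(z[qp.idx_xa])
        slack = tuple(float(s) for s in z[qp.idx_slack])
        u_seq = np.empty(cfg.Hp)
        u_seq[: cfg.Hu] = z[: cfg.Hu]
        u_seq[cfg.Hu :] = ua
        u_seq = np.clip(u_seq, zone.u_min, zone.u_max)
        dhat = np.atleast_1d(np.asarray(dhat, dtype=float))
        ya = float(aug.Ct[0, :NX] @ xa + aug.Ct[0, NX:] @ dhat)
        traj = self.predict_trajectory(xhat, dhat, u_seq)
        cost = dynamic_cost(traj[:-1], u_seq, xa, ua, cfg.Q, cfg.R)
        cost += terminal_cost(xa, ua, zone, dhat, aug, cfg.P)
        applied = float(u_seq[0])
        if cfg.dose_step:
            applied = round(applied / cfg.dose_step) * cfg.dose_step
            applied = float(np.clip(applied, zone.u_min, zone.u_max))
        status = "zone_relaxed" if max(slack) > 1e-6 else "optimal"
        return ControlSolution(
            u_seq=u_seq,
            xa=xa,
            ua=ua,
            ya=ya,
            cost=cost,
            status=status,
            applied=applied,
            slack=slack,
        )

    def control(self, xhat: StateVector, dhat) -> ControlSolution:
        """Build and solve the period's QP from the current estimates."""
        qp = self.build_qp(xhat, dhat)
        return self.solve(qp, xhat, dhat)

    def objective_constant(self, xhat, dhat) -> float:
        """Constant dropped from the condensed QP objective, so that
        ``qp_value + objective_constant`` equals the full cost expression
        (stage cost + slack penalty + regularizers) at any feasible point."""
        cfg, zone, aug = self.cfg, self.zone, self.aug
        xhat = np.asarray(xhat, dtype=float).reshape(NX)
        dhat = np.atleast_1d(np.asarray(dhat, dtype=float))
        w = aug.Bdd @ dhat + aug.imp.Ed
        cd = float(aug.Ct[0, NX:] @ dhat)
        const = 0.0
        for j in range(cfg.Hp):
            c_j = self._Phi[j] @ xhat + self._Cum[j] @ w
            const += float(c_j @ cfg.Q @ c_j)
        y_center = 0.5 * (zone.y_lo + zone.y_hi)
        const += cfg.center_weight * (cd - y_center) ** 2
        return const

    def regularization_value(self, z, dhat) -> float:
        """Ridge + zone-centre tie-break terms evaluated at a decision
        vector (the part of the QP objective beyond the formulation cost)."""
        cfg, zone, aug = self.cfg, self.zone, self.aug
        z = np.asarray(z, dtype=float)
        dhat = np.atleast_1d(np.asarray(dhat, dtype=float))
        cd = float(aug.Ct[0, NX:] @ dhat)
        ya = float(self._row_ya @ z) + cd
        y_center = 0.5 * (zone.y_lo + zone.y_hi)
        return cfg.ridge * float(z @ z) + cfg.center_weight * (ya - y_center) ** 2

    def predict_trajectory(self, xhat, dhat, u_seq) -> np.ndarray:
        """Roll the disturbance-corrected prediction model forward under a
        bolus sequence; returns states x(0..len(u_seq))."""
        imp = self.aug.imp
        dhat = np.atleast_1d(np.asarray(dhat, dtype=float))
        w = self.aug.Bdd @ dhat + imp.Ed
        B = imp.Bud
        x = np.asarray(xhat, dtype=float).reshape(NX)
        out = [x]
        for u in np.asarray(u_seq, dtype=float):
            x = imp.Ad @ x + B * u + w
            out.append(x)
        return np.array(out)


def closed_loop_step(
    plant_state: StateVector,
    estimator: KalmanEstimator,
    mpc: ZoneMPC,
    plant: ImpulsiveModel,
    meal_g: float = 0.0,
    cgm: float | None = None,
    *,
    clamp_floor: float = 1.0,
):
    """One full control cycle against the (possibly mismatched) plant.

    Order of operations: read the CGM sample -> measurement update ->
    solve the zone MPC -> apply the first bolus to the plant -> advance
    the plant one period with the true, unannounced meal (the controller
    and estimator always see ``r = 0``).  The plant's glycemia is clamped
    below at ``clamp_floor`` mg/dL; the prediction model never is.

    Returns ``(next_plant_state, estimate, solution, cgm_sample)``.
    """
    from .core_model import step as plant_step

    x = np.asarray(plant_state, dtype=float).reshape(NX)
    y = float(x[0]) if cgm is None else cgm
    filt = estimator.update(y)
    sol = mpc.control(filt.xhat, filt.dhat)
    estimator.predict(sol.applied, 0.0)
    x_next = plant_step(plant, x, u=sol.applied, r=meal_g)
    if x_next[0] < clamp_floor:
        x_next = x_next.copy()
        x_next[0] = clamp_floor
    return x_next, estimator.estimate, sol, y
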