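import itertools

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from ofzmpc.controller import (
    ControllerConfig,
    ZoneMPC,
    ZoneSpec,
    closed_loop_step,
    dynamic_cost,
    target_input_interval,
    terminal_cost,
)
from ofzmpc.core_model import NX, ImpulsiveModel, build_continuous, discretize
from ofzmpc.observer import AugmentedModel, DisturbanceModel

from conftest import make_loop


def equilibrium_for_ya(aug, ya, dhat=0.0):
    """Exact sampled equilibrium (x, u_dose) whose output equals ya."""
    imp = aug.imp
    d = np.atleast_1d(np.asarray(dhat, dtype=float))
    I_A = np.eye(NX) - imp.Ad
    w = aug.Bdd @ d + imp.Ed
    a = np.linalg.solve(I_A, w)
    bvec = np.linalg.solve(I_A, imp.Bud)
    cd = float(aug.Ct[0, NX:] @ d)
    u = (ya - cd - a[0]) / bvec[0]
    return a + bvec * u, float(u)


class TestZoneSpec:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ZoneSpec(y_lo=130, y_hi=90)
        with pytest.raises(ValueError):
            ZoneSpec(u_min=1.0, u_max=0.5)


class TestControllerConfig:
    def test_horizon_ordering(self):
        with pytest.raises(ValueError):
            ControllerConfig(Hp=10, Hu=20)

    def test_indefinite_q_rejected(self):
        Q = np.zeros((5, 5))
        Q[0, 0] = -1.0
        with pytest.raises(ValueError, match="semidefinite"):
            ControllerConfig(Q=Q)


class TestDynamicCost:
    def test_zero_at_equilibrium(self):
        xa = np.array([110.0, 0.1, 0.1, 0, 0])
        traj = np.tile(xa, (10, 1))
        u = np.full(10, 0.3)
        assert dynamic_cost(traj, u, xa, 0.3, np.eye(5), 2.0) == 0.0

    def test_single_step_deviation(self):
        Q = np.diag([1.0, 0, 0, 0, 0])
        xa = np.zeros(5)
        traj = np.zeros((4, 5))
        traj[2, 0] = 3.0
        assert dynamic_cost(traj, np.zeros(4), xa, 0.0, Q, 1.0) == pytest.approx(9.0)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        Q = rng.normal(size=(5, 5))
        Q = Q @ Q.T
        R = 3.7
        traj = rng.normal(size=(8, 5))
        u = rng.normal(size=8)
        xa = rng.normal(size=5)
        ua = 0.4
        expected = sum(
            (traj[j] - xa) @ Q @ (traj[j] - xa) + R * (u[j] - ua) ** 2
            for j in range(8)
        )
        assert dynamic_cost(traj, u, xa, ua, Q, R) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            dynamic_cost(np.zeros((3, 5)), np.zeros(4), np.zeros(5), 0, np.eye(5), 1)


class TestTerminalCost:
    def test_zero_at_target_equilibrium(self, dr1_aug):
        zone = ZoneSpec()
        xa, ua = equilibrium_for_ya(dr1_aug, 110.0)
        assert terminal_cost(xa, ua, zone, [0.0], dr1_aug, 1e4) == 0.0

    def test_monotone_in_violation(self, dr1_aug):
        zone = ZoneSpec()
        vals = []
        for ya in (140.0, 150.0, 160.0):
            xa, ua = equilibrium_for_ya(dr1_aug, ya)
            vals.append(terminal_cost(xa, ua, zone, [0.0], dr1_aug, 1e4))
        assert 0 < vals[0] < vals[1] < vals[2]
        assert vals[1] - vals[0] == pytest.approx(1e5)

    def test_matches_projection_qp_oracle(self, dr1_aug):
        # distance of ya to the zone == distance to its projection,
        # computed by an independent small QP
        zone = ZoneSpec()
        for ya in (75.0, 110.0, 162.5):
            xa, ua = equilibrium_for_ya(dr1_aug, ya)
            got = terminal_cost(xa, ua, zone, [0.0], dr1_aug, 1.0)
            proj = minimize(
                lambda v: (v[0] - ya) ** 2,
                [110.0],
                constraints=[LinearConstraint(np.eye(1), zone.y_lo, zone.y_hi)],
                method="SLSQP",
            )
            assert got == pytest.approx(abs(float(proj.x[0]) - ya), abs=1e-6)


class TestTargetInputInterval:
    def test_interval_brackets_zone(self, dr1_aug):
        zone = ZoneSpec()
        lo, hi = target_input_interval(dr1_aug, zone, [0.0])
        # doses at the ends map to the zone edges (insulin lowers glucose)
        _, u_hi_edge = equilibrium_for_ya(dr1_aug, zone.y_lo)
        _, u_lo_edge = equilibrium_for_ya(dr1_aug, zone.y_hi)
        assert lo == pytest.approx(u_lo_edge, abs=1e-12)
        assert hi == pytest.approx(u_hi_edge, abs=1e-12)

    def test_empty_when_unreachable(self, dr1_aug):
        # a huge positive disturbance pushes all feasible equilibria above
        # the zone: no admissible dose can hold the output inside
        zone = ZoneSpec(u_min=0.0, u_max=1e-6)
        assert target_input_interval(dr1_aug, zone, [100.0]) is None


class TestBuildQP:
    def test_dimensions_tiny_instance(self, dr1_aug):
        cfg = ControllerConfig(Hp=2, Hu=1)
        mpc = ZoneMPC(dr1_aug, ZoneSpec(), cfg)
        qp = mpc.build_qp(np.array([200.0, 0, 0, 0, 0]), [0.0])
        n = 1 + NX + 1 + 2  # u0, xa, ua, two slacks
        assert qp.H.shape == (n, n)
        assert qp.A_eq.shape == (10, n)  # terminal (5) + equilibrium (5)
        # zone (2) + boxes on u0 and ua (4) + slack positivity (2)
        assert qp.G_in.shape == (8, n)

    def test_zero_disturbance_reduces_to_nominal(self, dr1_aug):
        import dataclasses

        cfg = ControllerConfig(Hp=8, Hu=4)
        xhat = np.array([250.0, 0, 0, 0, 0])
        mpc = ZoneMPC(dr1_aug, ZoneSpec(), cfg)
        qp = mpc.build_qp(xhat, [0.0])
        nominal_aug = dataclasses.replace(dr1_aug, Bdd=np.zeros_like(dr1_aug.Bdd))
        qp0 = ZoneMPC(nominal_aug, ZoneSpec(), cfg).build_qp(xhat, [0.0])
        np.testing.assert_allclose(qp.H, qp0.H)
        np.testing.assert_allclose(qp.g, qp0.g)
        np.testing.assert_allclose(qp.b_eq, qp0.b_eq)
        np.testing.assert_allclose(qp.h_in, qp0.h_in)

    def test_objective_consistency_at_optimum(self, dr1_aug):
        # QP value (plus the dropped constant, minus the regularizers)
        # equals dynamic_cost + terminal_cost evaluated directly
        from ofzmpc import qp as qpmod

        cfg = ControllerConfig()
        zone = ZoneSpec()
        mpc = ZoneMPC(dr1_aug, zone, cfg)
        xhat = np.array([320.0, 0.001, 0.002, 0.0, 0.0])
        dhat = np.array([0.7])
        qp = mpc.build_qp(xhat, dhat)
        res = qpmod.solve_qp(qp.H, qp.g, qp.A_eq, qp.b_eq, qp.G_in, qp.h_in, max_iter=100)
        z = res.x
        full_value = res.fun + mpc.objective_constant(xhat, dhat)
        full_value -= mpc.regularization_value(z, dhat)
        sol = mpc.solve(qp, xhat, dhat)
        assert sol.status != "failed-safe"
        assert full_value == pytest.approx(sol.cost, rel=1e-4, abs=1e-2)


def scalar_test_rig(a=0.85, b=-40.0, e=20.0, T=5.0):
    """Hand-built effectively-scalar sampled model embedded in the 5-state
    frame (states 2..5 identically zero), for brute-force comparison."""
    Ad = np.zeros((NX, NX))
    Ad[0, 0] = a
    Bud = np.zeros(NX)
    Bud[0] = b
    imp = ImpulsiveModel(Ad=Ad, Bud=Bud, Brd=np.zeros(NX), Ed=np.r_[e, np.zeros(4)], T=T)
    Bdd = np.zeros((NX, 1))
    Bdd[0, 0] = 1.0
    dist = DisturbanceModel(Bd=Bdd, Cd=np.zeros((1, 1)))
    At = np.zeros((NX + 1, NX + 1))
    At[:NX, :NX] = Ad
    At[:NX, NX:] = Bdd
    At[NX, NX] = 1.0
    aug = AugmentedModel(
        At=At,
        But=np.r_[Bud, 0.0],
        Brt=np.zeros(NX + 1),
        Et=np.r_[e, np.zeros(5)],
        Ct=np.array([[1.0, 0, 0, 0, 0, 0]]),
        Bdd=Bdd,
        dist=dist,
        imp=imp,
    )
    return imp, aug


class TestBruteForceOracle:
    """Exhaustive grid search over the bolus sequence on a scalarized
    model: xa is pinned by the terminal equality and ua follows from the
    equilibrium equality in closed form, so every grid point is an exactly
    feasible candidate."""

    @pytest.mark.parametrize("x0,dval", [(300.0, 0.0), (150.0, 0.0), (220.0, 2.0)])
    def test_qp_matches_grid_optimum(self, x0, dval):
        a, b, e = 0.85, -40.0, 20.0
        imp, aug = scalar_test_rig(a, b, e)
        zone = ZoneSpec()
        cfg = ControllerConfig(Hp=3, Hu=3, R=1.0)
        mpc = ZoneMPC(aug, zone, cfg)
        xhat = np.r_[x0, np.zeros(4)]
        dhat = np.array([dval])
        sol = mpc.control(xhat, dhat)
        assert sol.status != "failed-safe"

        def candidate_cost(useq):
            x = x0
            traj = []
            for u in useq:
                traj.append(x)
                x = a * x + b * u + dval + e
            xa1 = x  # terminal equality
            ua = (xa1 * (1 - a) - e - dval) / b
            if not (zone.u_min - 1e-12 <= ua <= zone.u_max + 1e-12):
                return np.inf, None
            xa = np.r_[xa1, np.zeros(4)]
            c = dynamic_cost(
                np.array([np.r_[t, np.zeros(4)] for t in traj]), np.array(useq), xa, ua, cfg.Q, cfg.R
            )
            c += terminal_cost(xa, ua, zone, dhat, aug, cfg.P)
            z = np.r_[np.array(useq), xa, ua, 0.0, 0.0]
            c += mpc.regularization_value(z, dhat)
            return c, ua

        grid = np.linspace(zone.u_min, zone.u_max, 41)
        best = min(
            candidate_cost(u)[0] for u in itertools.product(grid, repeat=3)
        )
        sol_qp = mpc.build_qp(xhat, dhat)
        from ofzmpc import qp as qpmod

        res = qpmod.solve_qp(sol_qp.H, sol_qp.g, sol_qp.A_eq, sol_qp.b_eq, sol_qp.G_in, sol_qp.h_in)
        qp_value = res.fun + mpc.objective_constant(xhat, dhat)
        # optimum is no worse than the best grid point (up to solver
        # precision), and close to it
        assert qp_value <= best + 1e-6 * abs(best) + 1e-6
        assert qp_value == pytest.approx(best, rel=0.05, abs=5.0)


class TestSolve:
    def test_at_target_equilibrium_returns_equilibrium_dose(self, dr1_aug):
        zone = ZoneSpec()
        cfg = ControllerConfig()
        mpc = ZoneMPC(dr1_aug, zone, cfg)
        xa, ua = equilibrium_for_ya(dr1_aug, 110.0)  # 110 = zone centre
        sol = mpc.control(xa, [0.0])
        assert sol.status == "optimal"
        assert sol.applied == pytest.approx(ua, abs=1e-4)
        assert sol.cost == pytest.approx(0.0, abs=1e-3)
        assert sol.ya == pytest.approx(110.0, abs=0.01)

    def test_hyperglycemic_dose_exceeds_equilibrium_dose(self, dr1_aug):
        zone = ZoneSpec()
        mpc = ZoneMPC(dr1_aug, zone, ControllerConfig())
        sol = mpc.control(np.array([400.0, 0, 0, 0, 0]), [0.0])
        assert sol.status != "failed-safe"
        assert sol.applied > sol.ua
        assert sol.applied <= zone.u_max + 1e-9

    def test_applied_dose_always_within_bounds(self, dr3):
        _, _, mpc, _ = make_loop(dr3)
        rng = np.random.default_rng(11)
        for _ in range(20):
            xhat = np.r_[rng.uniform(40, 500), rng.uniform(0, 0.05, 2), rng.uniform(0, 0.2, 2)]
            sol = mpc.control(xhat, [rng.normal(0, 3)])
            assert 0.0 <= sol.applied <= 1.0

    def test_dose_quantization(self, dr1_aug):
        cfg = ControllerConfig(dose_step=0.05)
        mpc = ZoneMPC(dr1_aug, ZoneSpec(), cfg)
        sol = mpc.control(np.array([300.0, 0, 0, 0, 0]), [0.0])
        assert sol.applied == pytest.approx(round(sol.applied / 0.05) * 0.05, abs=1e-12)


class TestClosedLoop:
    def test_regulation_at_equilibrium_stays_in_zone(self, dr1, dr1_aug):
        imp, aug, mpc, est = make_loop(dr1)
        xa, ua = equilibrium_for_ya(aug, 110.0)
        x = xa.copy()
        est.estimate = est.estimate.with_z(np.r_[xa, 0.0])
        doses = []
        for _ in range(60):
            x, e, sol, y = closed_loop_step(x, est, mpc, imp)
            doses.append(sol.applied)
            assert 90.0 - 1e-6 <= y <= 130.0 + 1e-6
        assert np.allclose(doses[-10:], ua, atol=5e-4)

    def test_hyperglycemic_start_converges_no_offset(self, dr3):
        imp, aug, mpc, est = make_loop(dr3)
        est.estimate = est.estimate.with_z(np.r_[400.0, np.zeros(5)])
        x = np.array([400.0, 0, 0, 0, 0])
        ys = []
        for _ in range(150):
            x, e, sol, y = closed_loop_step(x, est, mpc, imp)
            ys.append(y)
        assert all(90.0 - 1e-3 <= v <= 130.0 + 1e-3 for v in ys[-50:])
        assert abs(ys[-1] - ys[-2]) < 1e-3  # stationary, no residual drift

    def test_offset_free_under_p2_inflation(self, dr3):
        # plant 30% more insulin-sensitive than the controller's model
        plant = discretize(build_continuous(dr3.perturbed({"p2": 1.3})), 5.0)
        _, aug, mpc, est = make_loop(dr3)
        est.estimate = est.estimate.with_z(np.r_[200.0, np.zeros(5)])
        x = np.array([200.0, 0, 0, 0, 0])
        for _ in range(250):
            x, e, sol, y = closed_loop_step(x, est, mpc, plant)
        assert 90.0 - 1e-3 <= x[0] <= 130.0 + 1e-3
        assert abs(e.innovation) < 1e-3

    def test_cost_nonincreasing_after_transient(self, dr1):
        imp, aug, mpc, est = make_loop(dr1)
        est.estimate = est.estimate.with_z(np.r_[300.0, np.zeros(5)])
        x = np.array([300.0, 0, 0, 0, 0])
        costs = []
        for _ in range(80):
            x, e, sol, y = closed_loop_step(x, est, mpc, imp)
            costs.append(sol.cost)
        tail = costs[10:]
        diffs = np.diff(tail)
        assert np.all(diffs <= abs(np.array(tail[:-1])) * 1e-3 + 1e-3)

    def test_zone_idempotence(self, dr1):
        # starting at a disturbance-corrected equilibrium inside the zone,
        # glucose is never driven out of the zone; the loop ends at a
        # target equilibrium (the centre-pull regularization may migrate
        # it within the zone, but the dose ends inside the target-
        # equilibrium dose interval)
        imp, aug, mpc, est = make_loop(dr1)
        xa, ua = equilibrium_for_ya(aug, 120.0)
        est.estimate = est.estimate.with_z(np.r_[xa, 0.0])
        x = xa.copy()
        lo, hi = target_input_interval(aug, ZoneSpec(), [0.0])
        doses = []
        for _ in range(80):
            x, e, sol, y = closed_loop_step(x, est, mpc, imp)
            assert 90.0 - 1e-6 <= y <= 130.0 + 1e-6
            doses.append(sol.applied)
        assert lo - 1e-3 <= doses[-1] <= hi + 1e-3

    def test_idle_at_centre_equilibrium(self, dr1):
        # at the zone-centre equilibrium the controller is exactly idle
        imp, aug, mpc, est = make_loop(dr1)
        xa, ua = equilibrium_for_ya(aug, 110.0)
        est.estimate = est.estimate.with_z(np.r_[xa, 0.0])
        x = xa.copy()
        for _ in range(40):
            x, e, sol, y = closed_loop_step(x, est, mpc, imp)
            assert sol.applied == pytest.approx(ua, abs=1e-3)
        assert x[0] == pytest.approx(110.0, abs=0.05)

    def test_failed_solver_injects_nothing(self, dr1_aug, monkeypatch):
        from ofzmpc import qp as qpmod
        from ofzmpc.qp import QPResult

        mpc = ZoneMPC(dr1_aug, ZoneSpec(), ControllerConfig())

        def broken(*a, **k):
            n = a[1].size if len(a) > 1 else 1
            return QPResult(
                x=np.full(n, np.nan), fun=np.nan, status="numerical_failure",
                iterations=0, eq_residual=np.inf, ineq_violation=np.inf,
            )

        monkeypatch.setattr("ofzmpc.controller.qpmod.solve_qp", broken)
        sol = mpc.control(np.array([400.0, 0, 0, 0, 0]), [0.0])
        assert sol.status == "failed-safe"
        assert sol.applied == 0.0
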