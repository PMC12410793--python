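"""Disturbance-augmented model and Kalman-type state/disturbance estimation.

The sampled model is augmented with an integrating disturbance ``d`` whose
injection points are chosen through ``Bd`` (state) and ``Cd`` (output):

    [x(k+1)]   [Ad  Bdd] [x(k)]   [Bud]        [Brd]        [Ed]
    [d(k+1)] = [0    I ] [d(k)] + [ 0 ] u(k) + [ 0 ] r(k) + [ 0 ],

    y(k) = C x(k) + Cd d(k),        Bdd = exp(A T) Bd.

Estimating ``(x, d)`` jointly lets a constant plant-model mismatch —
unannounced meals, wrong endogenous production, biased sensors — be
absorbed into ``d`` so the controller can correct both its prediction
model and its target equilibria.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm, solve_discrete_are

from .core_model import NX, ContinuousModel, ImpulsiveModel, dose_to_rate

__all__ = [
    "DisturbanceModel",
    "AugmentedModel",
    "AugmentedEstimate",
    "NoiseConfig",
    "input_disturbance",
    "output_disturbance",
    "augment",
    "observability_rank",
    "kalman_step",
    "KalmanEstimator",
]


@dataclass(frozen=True)
class DisturbanceModel:
    """Injection maps of the integrating disturbance.

    ``Bd`` is (5, nd), ``Cd`` is (1, nd); they may not both be zero.
    """

    Bd: np.ndarray
    Cd: np.ndarray

    def __post_init__(self) -> None:
        Bd = np.atleast_2d(np.asarray(self.Bd, dtype=float))
        Cd = np.atleast_2d(np.asarray(self.Cd, dtype=float))
        if Bd.shape[0] != NX:
            raise ValueError(f"Bd must have {NX} rows, got {Bd.shape}")
        if Cd.shape[0] != 1 or Cd.shape[1] != Bd.shape[1]:
            raise ValueError(
                f"Cd must be 1x{Bd.shape[1]} to match Bd, got {Cd.shape}"
            )
        if Bd.shape[1] < 1:
            raise ValueError("disturbance dimension nd must be >= 1")
        if not (Bd.any() or Cd.any()):
            raise ValueError("Bd and Cd may not both be zero")
        object.__setattr__(self, "Bd", Bd)
        object.__setattr__(self, "Cd", Cd)

    @property
    def nd(self) -> int:
        return self.Bd.shape[1]


def input_disturbance() -> DisturbanceModel:
    """Default structure: scalar mismatch entering the glycemia balance.

    This is where unannounced meals and endogenous-production error act;
    the output map is untouched.
    """
    Bd = np.zeros((NX, 1))
    Bd[0, 0] = 1.0
    return DisturbanceModel(Bd=Bd, Cd=np.zeros((1, 1)))


def output_disturbance() -> DisturbanceModel:
    """Alternative structure: scalar additive bias on the CGM output."""
    return DisturbanceModel(Bd=np.zeros((NX, 1)), Cd=np.ones((1, 1)))


@dataclass(frozen=True)
class AugmentedModel:
    """Block matrices of the disturbance-augmented sampled model."""

    At: np.ndarray      # (5+nd, 5+nd)
    But: np.ndarray     # (5+nd,)
    Brt: np.ndarray     # (5+nd,)
    Et: np.ndarray      # (5+nd,)
    Ct: np.ndarray      # (1, 5+nd)
    Bdd: np.ndarray     # (5, nd), exp(A T) Bd
    dist: DisturbanceModel
    imp: ImpulsiveModel

    @property
    def nd(self) -> int:
        return self.dist.nd

    @property
    def nx(self) -> int:
        return NX + self.nd


def augment(
    imp: ImpulsiveModel,
    dist: DisturbanceModel,
    *,
    continuous: ContinuousModel | None = None,
) -> AugmentedModel:
    """Assemble the augmented sampled model.

    ``Bdd = exp(A T) Bd`` needs the continuous state matrix; when it is not
    supplied it is rebuilt from the impulsive model's parameter set.
    """
    nd = dist.nd
    if continuous is None:
        if imp.params is None:
            raise ValueError(
                "augment() needs the continuous model (or an ImpulsiveModel "
                "carrying its parameters) to form exp(A T) Bd"
            )
        from .core_model import build_continuous

        continuous = build_continuous(imp.params)
    Bdd = expm(continuous.A * imp.T) @ dist.Bd

    n = NX + nd
    At = np.zeros((n, n))
    At[:NX, :NX] = imp.Ad
    At[:NX, NX:] = Bdd
    At[NX:, NX:] = np.eye(nd)
    But = np.concatenate([imp.Bud, np.zeros(nd)])
    Brt = np.concatenate([imp.Brd, np.zeros(nd)])
    Et = np.concatenate([imp.Ed, np.zeros(nd)])
    Ct = np.concatenate([continuous.C, dist.Cd], axis=1)
    return AugmentedModel(
        At=At, But=But, Brt=Brt, Et=Et, Ct=Ct, Bdd=Bdd, dist=dist, imp=imp
    )


def observability_rank(aug: AugmentedModel) -> tuple[int, bool]:
    """Rank of the stacked observability matrix of ``(At, Ct)``.

    Returns ``(rank, full_rank)``; full rank (= 5 + nd) is required for the
    joint state/disturbance estimate to be well posed.
    """
    n = aug.nx
    blocks = [aug.Ct]
    for _ in range(n - 1):
        blocks.append(blocks[-1] @ aug.At)
    obs = np.vstack(blocks)
    rank = int(np.linalg.matrix_rank(obs))
    return rank, rank == n


@dataclass(frozen=True)
class NoiseConfig:
    """Estimator covariances (none are reported for the in-vivo runs; these
    defaults put high confidence on the model states and a deliberately
    large weight on the plant-model difference ``d``)."""

    q_glycemia: float = 1e-2
    q_insulin: float = 1e-8
    q_meal: float = 1e-10
    q_disturbance: float = 5e-2
    r_measurement: float = 25.0  # (5 mg/dL CGM error scale)^2
    p0_state: float = 1e2
    p0_disturbance: float = 1e2

    def process_matrix(self, nd: int) -> np.ndarray:
        diag = [self.q_glycemia] + [self.q_insulin] * 2 + [self.q_meal] * 2
        diag += [self.q_disturbance] * nd
        return np.diag(diag)

    def initial_covariance(self, nd: int) -> np.ndarray:
        diag = [self.p0_state] * NX + [self.p0_disturbance] * nd
        return np.diag(diag)


@dataclass(frozen=True)
class AugmentedEstimate:
    """Joint estimate: a priori state/disturbance, covariance, last gain."""

    xhat: np.ndarray          # (5,) state estimate
    dhat: np.ndarray          # (nd,) disturbance estimate
    P_cov: np.ndarray         # (5+nd, 5+nd)
    L: np.ndarray | None = None
    innovation: float | None = None
    corrected: bool = True    # False after a dropout (prediction-only step)

    @property
    def z(self) -> np.ndarray:
        return np.concatenate([self.xhat, self.dhat])

    def with_z(self, z: np.ndarray, **kw) -> "AugmentedEstimate":
        return replace(self, xhat=z[:NX], dhat=z[NX:], **kw)


class KalmanEstimator:
    """Time-varying (or steady-state) Kalman filter on the augmented model.

    The per-period cycle is split so the controller can act on the
    measurement it just received:

    ``update(y)``   filtered estimate from the innovation ``y - Ct z``,
    ``predict(u,r)`` a priori estimate for the next period.

    Composing the two reproduces the one-line predictor recursion
    ``z(k+1) = At z(k) + But u + Brt r + Et + L (y - Ct z(k))`` with
    ``L = At Kf``.  A missing sample (CGM dropout) skips the correction and
    flags the estimate as prediction-only.
    """

    def __init__(
        self,
        aug: AugmentedModel,
        noise: NoiseConfig | None = None,
        *,
        gain_mode: str = "time-varying",
        y0: float | None = None,
    ):
        if gain_mode not in ("time-varying", "steady-state"):
            raise ValueError(f"unknown gain_mode {gain_mode!r}")
        rank, full = observability_rank(aug)
        if not full:
            raise ValueError(
                f"augmented model is unobservable (rank {rank} < {aug.nx}); "
                "choose Bd/Cd making the disturbance visible at the output"
            )
        self.aug = aug
        self.noise = noise or NoiseConfig()
        self.Qn = self.noise.process_matrix(aug.nd)
        self.Rn = float(self.noise.r_measurement)
        if self.Rn <= 0 or np.any(np.diag(self.Qn) < 0):
            raise ValueError("noise covariances must be positive (semi)definite")
        self.gain_mode = gain_mode
        self._Pss = None
        if gain_mode == "steady-state":
            self._Pss = solve_discrete_are(
                aug.At.T, aug.Ct.T, self.Qn, np.array([[self.Rn]])
            )
        xhat = np.zeros(NX)
        if y0 is not None:
            xhat[0] = float(y0)
        P0 = self._Pss if self._Pss is not None else self.noise.initial_covariance(aug.nd)
        self.estimate = AugmentedEstimate(
            xhat=xhat, dhat=np.zeros(aug.nd), P_cov=P0.copy()
        )

    # -- one full predictor-form cycle ---------------------------------
    def step(self, y: float | None, u_dose: float, r_grams: float = 0.0) -> AugmentedEstimate:
        """Ingest measurement ``y`` (or None on dropout), then the applied
        bolus/meal, returning the a priori estimate for the next period."""
        self.update(y)
        return self.predict(u_dose, r_grams)

    def update(self, y: float | None) -> AugmentedEstimate:
        aug, est = self.aug, self.estimate
        if y is None or (isinstance(y, float) and not np.isfinite(y)):
            self.estimate = replace(est, innovation=None, corrected=False)
            return self.estimate
        P = est.P_cov if self.gain_mode == "time-varying" else self._Pss
        S = float((aug.Ct @ P @ aug.Ct.T).item()) + self.Rn
        Kf = (P @ aug.Ct.T / S).reshape(-1)
        innov = float(y) - float((aug.Ct @ est.z).item())
        z = est.z + Kf * innov
        P_new = P - np.outer(Kf, aug.Ct @ P)
        P_new = 0.5 * (P_new + P_new.T)
        self.estimate = est.with_z(
            z, P_cov=P_new, L=aug.At @ Kf, innovation=innov, corrected=True
        )
        return self.estimate

    def predict(self, u_dose: float, r_grams: float = 0.0) -> AugmentedEstimate:
        aug, est = self.aug, self.estimate
        r_rate = dose_to_rate(r_grams, aug.imp.T)
        z = aug.At @ est.z + aug.But * float(u_dose) + aug.Brt * r_rate + aug.Et
        P = aug.At @ est.P_cov @ aug.At.T + self.Qn
        self.estimate = est.with_z(z, P_cov=0.5 * (P + P.T))
        return self.estimate

    # -- diagnostics ----------------------------------------------------
    def steady_state_gain(self) -> np.ndarray:
        """Predictor gain at the Riccati fixed point, L = At P Ct' / S."""
        P = self._Pss
        if P is None:
            P = solve_discrete_are(
                self.aug.At.T, self.aug.Ct.T, self.Qn, np.array([[self.Rn]])
            )
        S = float((self.aug.Ct @ P @ self.aug.Ct.T).item()) + self.Rn
        return (self.aug.At @ P @ self.aug.Ct.T / S).reshape(-1)

    def error_spectral_radius(self) -> float:
        """Spectral radius of ``At - L Ct`` at the converged gain (< 1 iff
        the estimator is stable)."""
        L = self.steady_state_gain()
        M = self.aug.At - np.outer(L, self.aug.Ct.reshape(-1))
        return float(np.max(np.abs(np.linalg.eigvals(M))))


def kalman_step(
    estimator: KalmanEstimator,
    y: float | None,
    u_dose: float,
    r_grams: float = 0.0,
) -> AugmentedEstimate:
    """Functional wrapper over :meth:`KalmanEstimator.step`."""
    return estimator.step(y, u_dose, r_grams)
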