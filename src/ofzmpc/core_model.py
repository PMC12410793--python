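"""Five-compartment glucose-insulin model and its impulsive sampled form.

The continuous-time plant is linear,

    dx/dt = A x + Bu u + Br r + E,      y = C x,

with states x1 (glycemia, mg/dL), x2/x3 (insulin delivery rates in the
blood and subcutaneous compartments, U/min) and x4/x5 (carbohydrate
delivery rates in stomach and gut, g/min).  Insulin boluses are delivered
as impulses every ``T`` minutes, which yields the sampled-time recursion

    x(k+1) = Ad x(k) + Bud u(k) + Brd r(k) + Ed,

with Ad = exp(A T), Bud = exp(A T) Bu, Brd = (int_0^T exp(A s) ds) Br and
Ed = (int_0^T exp(A s) ds) E.

Input conventions: an insulin bolus is an impulse at the sampling instant,
so a dose of ``D`` units enters the recursion directly as ``Bud * D``
(the state jump ``Bu * D`` propagated over the period).  This is the
convention under which delivering the per-period equivalent ``D = T u*``
of a continuous basal rate ``u*`` (U/min) holds the corresponding rest
glycemia to well under 1%, and under which closed-loop dose totals match
in-vivo accounting.  A meal of ``g`` grams is spread over its sampling
interval as the rate ``r = g / T`` through the integrated map ``Brd``,
which conserves carbohydrate mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ModelParameters",
    "StateVector",
    "ContinuousModel",
    "ImpulsiveModel",
    "build_continuous",
    "discretize",
    "step",
    "continuous_equilibrium",
    "dose_to_rate",
    "rate_to_dose",
    "load_cohort_parameters",
    "FIXED_P3",
    "FIXED_P5",
]

NX = 5

#: Carbohydrate bioavailability (mg/dL/g) and time-to-max glucose
#: appearance (min) held fixed during identification.
FIXED_P3 = 9.5
FIXED_P5 = 20.45


class ParameterError(ValueError):
    """Raised when a physiological parameter violates its validity range."""


@dataclass(frozen=True)
class ModelParameters:
    """The six physiological constants defining one subject.

    Attributes
    ----------
    p0 : endogenous glucose production at zero insulin (mg/dL/min)
    p1 : hepatic autoregulation (1/min)
    p2 : insulin sensitivity (mg/dL/U)
    p3 : carbohydrate bioavailability (mg/dL/g)
    p4 : time-to-maximum effective insulin concentration (min)
    p5 : time-to-maximum appearance rate of glucose (min)

    ``p1 == 0`` is tolerated (two cohort fixtures print a zero after
    rounding); everything that relies on the zero-insulin rest point
    ``p0 / p1`` must handle that case explicitly.
    """

    p0: float
    p1: float
    p2: float
    p3: float = FIXED_P3
    p4: float = 100.0 / 9.0
    p5: float = FIXED_P5

    def __post_init__(self) -> None:
        for name in ("p0", "p2", "p3", "p4", "p5"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ParameterError(
                    f"parameter {name} must be strictly positive, got {value!r}"
                )
        if not np.isfinite(self.p1) or self.p1 < 0.0:
            raise ParameterError(
                f"parameter p1 must be non-negative, got {self.p1!r}"
            )

    @property
    def has_zero_p1(self) -> bool:
        """True when hepatic autoregulation is (rounded to) zero.

        With ``p1 == 0`` glycemia integrates its net input and the
        zero-insulin equilibrium ``p0 / p1`` does not exist.
        """
        return self.p1 == 0.0

    def zero_insulin_glycemia(self) -> float:
        """Rest glycemia ``p0 / p1`` with no insulin and no meals (mg/dL)."""
        if self.has_zero_p1:
            raise ParameterError(
                "p1 is zero: glycemia has no finite zero-insulin rest point"
            )
        return self.p0 / self.p1

    def as_dict(self) -> dict[str, float]:
        return {f"p{i}": float(getattr(self, f"p{i}")) for i in range(6)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParameters":
        known = {f"p{i}" for i in range(6)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def perturbed(self, factors: dict[str, float]) -> "ModelParameters":
        """Return a copy with selected parameters scaled multiplicatively."""
        values = self.as_dict()
        for name, factor in factors.items():
            if name not in values:
                raise ParameterError(f"unknown parameter {name!r}")
            values[name] = values[name] * float(factor)
        return ModelParameters.from_dict(values)


#: Plain 5-vector state; index 0 is glycemia x1 (documentation and error
#: messages use the 1-based names x1..x5).
StateVector = np.ndarray


def _as_state(x, *, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape != (NX,):
        raise ValueError(f"{name} must have {NX} components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries: {x}")
    return x


@dataclass(frozen=True)
class ContinuousModel:
    """Continuous-time matrices (A, Bu, Br, E, C) of the compartment model."""

    A: np.ndarray
    Bu: np.ndarray
    Br: np.ndarray
    E: np.ndarray
    C: np.ndarray
    params: ModelParameters


@dataclass(frozen=True)
class ImpulsiveModel:
    """Sampled-time matrices of the impulsive recursion with period ``T`` min."""

    Ad: np.ndarray
    Bud: np.ndarray
    Brd: np.ndarray
    Ed: np.ndarray
    T: float
    params: ModelParameters | None = field(default=None, compare=False)


def build_continuous(params: ModelParameters) -> ContinuousModel:
    """Assemble the continuous model matrices from physiological parameters.

    The state matrix couples glycemia to the blood-compartment insulin rate
    (gain ``-p2``) and to the gut carbohydrate rate (gain ``p3``); insulin
    and carbohydrate absorption are two-compartment first-order chains with
    time constants ``p4`` and ``p5``.
    """
    if not isinstance(params, ModelParameters):
        params = ModelParameters.from_dict(dict(params))
    p0, p1, p2, p3, p4, p5 = (getattr(params, f"p{i}") for i in range(6))
    A = np.array(
        [
            [-p1, -p2, 0.0, p3, 0.0],
            [0.0, -1.0 / p4, 1.0 / p4, 0.0, 0.0],
            [0.0, 0.0, -1.0 / p4, 0.0, 0.0],
            [0.0, 0.0, 0.0, -1.0 / p5, 1.0 / p5],
            [0.0, 0.0, 0.0, 0.0, -1.0 / p5],
        ]
    )
    Bu = np.array([0.0, 0.0, 1.0 / p4, 0.0, 0.0])
    Br = np.array([0.0, 0.0, 0.0, 0.0, 1.0 / p5])
    E = np.array([p0, 0.0, 0.0, 0.0, 0.0])
    C = np.array([[1.0, 0.0, 0.0, 0.0, 0.0]])
    return ContinuousModel(A=A, Bu=Bu, Br=Br, E=E, C=C, params=params)


def _expm_and_integral(A: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Return ``exp(A T)`` and ``int_0^T exp(A s) ds``.

    Both come out of one exponential of the augmented block matrix
    ``[[A, I], [0, 0]]`` scaled by ``T``, which is exact and does not
    require A to be invertible.
    """
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = A
    M[:n, n:] = np.eye(n)
    phi = expm(M * T)
    return phi[:n, :n], phi[:n, n:]


def discretize(model: ContinuousModel, T: float) -> ImpulsiveModel:
    """Sample the continuous model at impulse period ``T`` (minutes)."""
    T = float(T)
    if not np.isfinite(T) or T <= 0.0:
        raise ValueError(f"impulse period T must be positive, got {T!r}")
    Ad, S = _expm_and_integral(model.A, T)
    return ImpulsiveModel(
        Ad=Ad,
        Bud=Ad @ model.Bu,
        Brd=S @ model.Br,
        Ed=S @ model.E,
        T=T,
        params=model.params,
    )


def dose_to_rate(dose_u: float, T: float) -> float:
    """Convert a bolus of ``dose_u`` units over period ``T`` to U/min."""
    return float(dose_u) / float(T)


def rate_to_dose(rate: float, T: float) -> float:
    """Convert a basal rate in U/min to its per-period bolus in U."""
    return float(rate) * float(T)


def step(
    imp: ImpulsiveModel,
    x: StateVector,
    u: float = 0.0,
    r: float = 0.0,
) -> StateVector:
    """Advance one impulse period.

    Parameters
    ----------
    u : insulin bolus delivered this period (U, non-negative).
    r : carbohydrates ingested this period (g, non-negative).
    """
    x = _as_state(x)
    if u < 0.0:
        raise ValueError(f"insulin bolus u must be non-negative, got {u!r}")
    if r < 0.0:
        raise ValueError(f"meal r must be non-negative, got {r!r}")
    r_rate = dose_to_rate(r, imp.T)
    return imp.Ad @ x + imp.Bud * float(u) + imp.Brd * r_rate + imp.Ed


def continuous_equilibrium(
    params: ModelParameters, y_target: float
) -> tuple[StateVector, float]:
    """Constant-input rest point of the continuous model at a glycemia target.

    Returns the state ``(y_target, u*, u*, 0, 0)`` and the basal rate
    ``u* = (p0 - p1 * y_target) / p2`` in U/min.  Raises if the target
    would require a negative insulin rate.
    """
    y_target = float(y_target)
    if y_target < 0.0:
        raise ValueError(f"y_target must be non-negative, got {y_target!r}")
    u_star = (params.p0 - params.p1 * y_target) / params.p2
    if u_star < 0.0:
        raise ValueError(
            f"y_target={y_target} mg/dL exceeds the zero-insulin glycemia "
            f"{params.zero_insulin_glycemia():.2f} mg/dL: holding it would "
            "require a negative insulin rate"
        )
    x = np.array([y_target, u_star, u_star, 0.0, 0.0])
    return x, float(u_star)


def load_cohort_parameters() -> dict[str, ModelParameters]:
    """Packaged per-subject parameter sets of the 13-rat cohort.

    p3 and p5 are the fixed values used throughout identification; p0, p1,
    p2, p4 carry the printed (2-decimal) per-subject estimates.  Two
    subjects (DR7, DR11) print ``p1 = 0.00``; see ``ModelParameters.has_zero_p1``.
    """
    import pandas as pd

    with resources.files("ofzmpc.data").joinpath("rat_cohort_parameters.csv").open() as fh:
        table = pd.read_csv(fh)
    out: dict[str, ModelParameters] = {}
    for row in table.itertuples(index=False):
        out[str(row.subject)] = ModelParameters(
            p0=float(row.p0),
            p1=float(row.p1),
            p2=float(row.p2),
            p3=FIXED_P3,
            p4=float(row.p4),
            p5=FIXED_P5,
        )
    return out
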