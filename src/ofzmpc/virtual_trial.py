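"""Virtual-subject closed-loop trials.

Builds a 'true' plant (optionally mismatched against the controller's
model), feeds it unannounced meals, corrupts the CGM channel, and runs the
estimator + zone MPC cycle at the 5-minute cadence.  A 72-hour run
produces exactly 864 bolus decisions.

Randomness is centralized: one seed spawns named substreams (meals,
sensor, stress) so each component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controller import ControllerConfig, ZoneMPC, ZoneSpec, closed_loop_step
from .core_model import ModelParameters, build_continuous, discretize
from .observer import DisturbanceModel, KalmanEstimator, NoiseConfig, augment, input_disturbance

__all__ = [
    "MealSchedule",
    "SensorModel",
    "MismatchSpec",
    "ClosedLoopTrace",
    "generate_meals",
    "corrupt_cgm",
    "run_trial",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = [
    "time_min",
    "glucose_true",
    "cgm",
    "cgm_missing",
    "insulin_U",
    "meal_g",
    "projection_5min",
    "x2",
    "x3",
    "x4",
    "x5",
    "d_hat",
    "solver_status",
]


@dataclass(frozen=True)
class MealSchedule:
    """Unannounced meal events: (time in minutes, carbohydrates in grams)."""

    events: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("meal times must be strictly increasing")

    def grams_in_interval(self, t0: float, t1: float) -> float:
        """Total carbohydrates landing in [t0, t1)."""
        return float(sum(g for t, g in self.events if t0 <= t < t1))

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class SensorModel:
    """CGM corruption: dropouts, spike outliers, additive noise, quantization."""

    dropout_prob: float = 0.0
    outlier_prob: float = 0.0
    outlier_magnitude: float = 100.0  # mg/dL
    noise_sd: float = 0.0             # mg/dL
    quantization: float = 0.0         # mg/dL per step, 0 = off

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "outlier_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("outlier_magnitude", "noise_sd", "quantization"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MismatchSpec:
    """Multiplicative plant-side parameter perturbations, e.g.
    ``MismatchSpec({"p2": 1.3})`` inflates the true insulin sensitivity by
    30% relative to the controller's model."""

    factors: dict = field(default_factory=dict)

    def apply(self, params: ModelParameters) -> ModelParameters:
        return params.perturbed(self.factors) if self.factors else params


@dataclass
class ClosedLoopTrace:
    """Uniform-grid record of one closed-loop run."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trace is missing columns: {missing}")
        dt = np.diff(self.frame["time_min"].to_numpy())
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("trace must be on a uniform time grid")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def glucose(self) -> np.ndarray:
        return self.frame["glucose_true"].to_numpy()

    @property
    def cgm(self) -> np.ndarray:
        return self.frame["cgm"].to_numpy()

    @property
    def insulin(self) -> np.ndarray:
        return self.frame["insulin_U"].to_numpy()

    @property
    def total_insulin(self) -> float:
        return float(self.frame["insulin_U"].sum())

    @property
    def period(self) -> float:
        t = self.frame["time_min"].to_numpy()
        return float(t[1] - t[0]) if len(t) > 1 else float("nan")


def _substreams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_meals(
    seed: int | np.random.Generator,
    duration_min: float,
    *,
    gap_range: tuple[float, float] = (120.0, 240.0),
    gram_range: tuple[float, float] = (1.0, 5.0),
) -> MealSchedule:
    """Sporadic carbohydrate intakes: gaps uniform on [2, 4] hours, sizes
    uniform on [1, 5] g, until the duration is exhausted."""
    if duration_min < 0:
        raise ValueError("duration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[tuple[float, float]] = []
    t = float(rng.uniform(*gap_range))
    while t < duration_min:
        events.append((t, float(rng.uniform(*gram_range))))
        t += float(rng.uniform(*gap_range))
    return MealSchedule(events=tuple(events))


def corrupt_cgm(
    clean: np.ndarray,
    sensor: SensorModel,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the sensor model to a clean glucose series.

    Returns ``(values, missing)`` where dropped samples carry NaN and a
    True missing flag.  Corruption order: additive noise, then outlier
    spikes (random sign), then quantization, then dropouts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = np.asarray(clean, dtype=float)
    y = clean.copy()
    n = y.size
    if sensor.noise_sd > 0:
        y = y + rng.normal(0.0, sensor.noise_sd, size=n)
    if sensor.outlier_prob > 0:
        hit = rng.random(n) < sensor.outlier_prob
        signs = rng.choice([-1.0, 1.0], size=n)
        y = y + hit * signs * sensor.outlier_magnitude
    if sensor.quantization > 0:
        y = np.round(y / sensor.quantization) * sensor.quantization
    missing = np.zeros(n, dtype=bool)
    if sensor.dropout_prob > 0:
        missing = rng.random(n) < sensor.dropout_prob
        y = np.where(missing, np.nan, y)
    return y, missing


def run_trial(
    plant_params: ModelParameters,
    mismatch: MismatchSpec | None = None,
    controller_cfg: ControllerConfig | None = None,
    zone: ZoneSpec | None = None,
    meals: MealSchedule | None = None,
    sensor: SensorModel | None = None,
    *,
    duration_min: float = 72 * 60.0,
    initial_glycemia: float = 400.0,
    seed: int = 0,
    disturbance: DisturbanceModel | None = None,
    noise_cfg: NoiseConfig | None = None,
    estimator_gain_mode: str = "time-varying",
    generate_meal_schedule: bool = False,
) -> ClosedLoopTrace:
    """Run one virtual closed-loop trial.

    ``plant_params`` parameterize the controller's model; the true plant
    uses the same parameters with ``mismatch`` applied.  72 h at T = 5 min
    gives 864 control cycles.  Fully determined by ``(seed, config)``.
    """
    cfg = controller_cfg or ControllerConfig()
    zone = zone or ZoneSpec()
    sensor = sensor or SensorModel()
    streams = _substreams(seed, "meals", "sensor", "stress")
    if meals is None:
        meals = (
            generate_meals(streams["meals"], duration_min)
            if generate_meal_schedule
            else MealSchedule(events=())
        )

    true_params = (mismatch or MismatchSpec()).apply(plant_params)
    plant = discretize(build_continuous(true_params), cfg.T)
    model = discretize(build_continuous(plant_params), cfg.T)
    dist = disturbance or input_disturbance()
    aug = augment(model, dist)
    mpc = ZoneMPC(aug, zone, cfg)

    n_steps = int(round(duration_min / cfg.T))
    x = np.array([float(initial_glycemia), 0.0, 0.0, 0.0, 0.0])

    # Pre-draw the whole sensor corruption pattern so the sensor stream is
    # independent of the closed-loop evolution's control flow.
    sensor_rng = streams["sensor"]
    noise = sensor_rng.normal(0.0, 1.0, size=n_steps)
    out_hits = sensor_rng.random(n_steps)
    out_signs = sensor_rng.choice([-1.0, 1.0], size=n_steps)
    drops = sensor_rng.random(n_steps)

    estimator = KalmanEstimator(
        aug, noise_cfg, gain_mode=estimator_gain_mode, y0=initial_glycemia
    )

    records = []
    for k in range(n_steps):
        t = k * cfg.T
        y_true = float(x[0])
        y = y_true + sensor.noise_sd * noise[k]
        if sensor.outlier_prob > 0 and out_hits[k] < sensor.outlier_prob:
            y += out_signs[k] * sensor.outlier_magnitude
        if sensor.quantization > 0:
            y = round(y / sensor.quantization) * sensor.quantization
        is_missing = sensor.dropout_prob > 0 and drops[k] < sensor.dropout_prob

        meal_g = meals.grams_in_interval(t, t + cfg.T)
        x_next, est, sol, _ = closed_loop_step(
            x, estimator, mpc, plant, meal_g=meal_g, cgm=None if is_missing else y
        )
        # Model projection one period ahead from the post-measurement
        # estimate and the bolus actually applied (what MedARD compares
        # against the next CGM sample).
        proj = float(est.xhat[0])

        records.append(
            {
                "time_min": t,
                "glucose_true": y_true,
                "cgm": np.nan if is_missing else y,
                "cgm_missing": bool(is_missing),
                "insulin_U": sol.applied,
                "meal_g": meal_g,
                "projection_5min": proj,
                "x2": x[1],
                "x3": x[2],
                "x4": x[3],
                "x5": x[4],
                "d_hat": float(est.dhat[0]) if est.dhat.size else 0.0,
                "solver_status": sol.status,
            }
        )
        x = x_next

    return ClosedLoopTrace(frame=pd.DataFrame.from_records(records, columns=TRACE_COLUMNS))
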