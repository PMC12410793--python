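import numpy as np
import pytest

from ofzmpc.controller import ControllerConfig, ZoneMPC, ZoneSpec
from ofzmpc.core_model import (
    ModelParameters,
    build_continuous,
    discretize,
    load_cohort_parameters,
)
from ofzmpc.identification import BolusResponseDataset, simulate_response
from ofzmpc.observer import KalmanEstimator, augment, input_disturbance


@pytest.fixture(scope="session")
def cohort():
    return load_cohort_parameters()


@pytest.fixture(scope="session")
def dr1(cohort):
    return cohort["DR1"]


@pytest.fixture(scope="session")
def dr3(cohort):
    return cohort["DR3"]


@pytest.fixture
def dr1_imp(dr1):
    return discretize(build_continuous(dr1), 5.0)


@pytest.fixture
def dr1_aug(dr1_imp):
    return augment(dr1_imp, input_disturbance())


def random_params(rng: np.random.Generator) -> ModelParameters:
    """Physiologically plausible random parameter draw."""
    return ModelParameters(
        p0=rng.uniform(0.5, 20.0),
        p1=rng.uniform(0.002, 0.1),
        p2=rng.uniform(100.0, 2000.0),
        p3=9.5,
        p4=rng.uniform(2.0, 60.0),
        p5=rng.uniform(5.0, 40.0),
    )


def bolus_dataset(
    params: ModelParameters,
    n: int = 80,
    y0: float = 350.0,
    boluses=((0, 1.0), (30, 0.7), (55, 0.4)),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BolusResponseDataset:
    """Synthetic bolus-response window generated from the forward model."""
    times = np.arange(n) * 5.0
    doses = np.zeros(n)
    for k, d in boluses:
        doses[k] = d
    shell = BolusResponseDataset(times=times, cgm=np.full(n, y0), doses=doses)
    cgm = simulate_response(params, shell)
    if noise_sd > 0:
        cgm = cgm + (rng or np.random.default_rng(0)).normal(0.0, noise_sd, n)
    return BolusResponseDataset(times=times, cgm=cgm, doses=doses)


def make_loop(params, zone=None, cfg=None, noise=None):
    """Controller + estimator wired to the nominal model of ``params``."""
    cfg = cfg or ControllerConfig()
    imp = discretize(build_continuous(params), cfg.T)
    aug = augment(imp, input_disturbance())
    mpc = ZoneMPC(aug, zone or ZoneSpec(), cfg)
    est = KalmanEstimator(aug, noise, y0=None)
    return imp, aug, mpc, est
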