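"""Run configuration: YAML tree with documented defaults and provenance.

Every key has a default; user files may override any subset.  Unknown keys
are rejected.  ``Config.provenance`` records, per dotted key, whether the
value came from the defaults or the user file — the run manifest logs it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import yaml

from .controller import ControllerConfig, ZoneSpec
from .observer import DisturbanceModel, NoiseConfig, input_disturbance, output_disturbance
from .virtual_trial import SensorModel

__all__ = ["Config", "load_config", "DEFAULTS"]

DEFAULTS: dict = {
    "controller": {
        "Hp": 100,
        "Hu": 30,
        "T": 5.0,
        "q_glycemia": 1.0,
        "R": 10.0,
        "P": 1.0e4,
        "ridge": 1.0e-7,
        "center_weight": 5.0,
        "dose_step": None,
    },
    "zone": {
        "y_lo": 90.0,
        "y_hi": 130.0,
        "u_min": 0.0,
        "u_max": 1.0,
    },
    "estimator": {
        "disturbance": "input",  # input | output
        "gain_mode": "time-varying",  # time-varying | steady-state
        "q_glycemia": 1.0e-2,
        "q_insulin": 1.0e-8,
        "q_meal": 1.0e-10,
        "q_disturbance": 5.0e-2,
        "r_measurement": 25.0,
    },
    "scenario": {
        "duration_min": 4320.0,
        "initial_glycemia": 400.0,
        "meals": True,
        "meal_gap_min": [120.0, 240.0],
        "meal_grams": [1.0, 5.0],
        "sensor": {
            "dropout_prob": 0.0,
            "outlier_prob": 0.0,
            "outlier_magnitude": 100.0,
            "noise_sd": 0.0,
            "quantization": 0.0,
        },
        "mismatch": {},
    },
    "fit": {
        "global_budget": 200,
        "local_max_iter": 40,
        "smoothing_factor": 0.25,
        "hampel_window": 7,
        "hampel_threshold": 3.0,
    },
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, prefix: str, provenance: dict) -> dict:
    out = {}
    for key, dval in defaults.items():
        dotted = f"{prefix}{key}"
        if user is not None and key in user:
            uval = user[key]
            if isinstance(dval, dict) and key != "mismatch":
                if not isinstance(uval, dict):
                    raise ConfigError(f"{dotted}: expected a mapping")
                out[key] = _merge(dval, uval, dotted + ".", provenance)
            else:
                out[key] = copy.deepcopy(uval)
                provenance[dotted] = "user"
        else:
            if isinstance(dval, dict) and key != "mismatch":
                out[key] = _merge(dval, None, dotted + ".", provenance)
            else:
                out[key] = copy.deepcopy(dval)
                provenance[dotted] = "default"
    if user:
        unknown = set(user) - set(defaults)
        if unknown:
            raise ConfigError(
                f"unknown configuration keys under "
                f"{prefix.rstrip('.') or 'top level'}: {sorted(unknown)}"
            )
    return out


@dataclass
class Config:
    data: dict
    provenance: dict

    # -- builders ------------------------------------------------------
    def controller(self) -> ControllerConfig:
        c = self.data["controller"]
        Q = np.zeros((5, 5))
        Q[0, 0] = float(c["q_glycemia"])
        return ControllerConfig(
            Hp=int(c["Hp"]),
            Hu=int(c["Hu"]),
            T=float(c["T"]),
            Q=Q,
            R=float(c["R"]),
            P=float(c["P"]),
            ridge=float(c["ridge"]),
            center_weight=float(c["center_weight"]),
            dose_step=None if c["dose_step"] in (None, 0) else float(c["dose_step"]),
        )

    def zone(self) -> ZoneSpec:
        z = self.data["zone"]
        return ZoneSpec(
            y_lo=float(z["y_lo"]),
            y_hi=float(z["y_hi"]),
            u_min=float(z["u_min"]),
            u_max=float(z["u_max"]),
        )

    def disturbance(self) -> DisturbanceModel:
        mode = self.data["estimator"]["disturbance"]
        if mode == "input":
            return input_disturbance()
        if mode == "output":
            return output_disturbance()
        raise ConfigError(f"estimator.disturbance must be input|output, got {mode!r}")

    def noise(self) -> NoiseConfig:
        e = self.data["estimator"]
        return NoiseConfig(
            q_glycemia=float(e["q_glycemia"]),
            q_insulin=float(e["q_insulin"]),
            q_meal=float(e["q_meal"]),
            q_disturbance=float(e["q_disturbance"]),
            r_measurement=float(e["r_measurement"]),
        )

    def gain_mode(self) -> str:
        return str(self.data["estimator"]["gain_mode"])

    def sensor(self) -> SensorModel:
        s = self.data["scenario"]["sensor"]
        return SensorModel(
            dropout_prob=float(s["dropout_prob"]),
            outlier_prob=float(s["outlier_prob"]),
            outlier_magnitude=float(s["outlier_magnitude"]),
            noise_sd=float(s["noise_sd"]),
            quantization=float(s["quantization"]),
        )

    def mismatch_factors(self) -> dict:
        return dict(self.data["scenario"]["mismatch"] or {})


def load_config(path=None) -> Config:
    """Load a YAML config file (or None for all defaults)."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        user = loaded
    provenance: dict = {}
    data = _merge(DEFAULTS, user, "", provenance)
    return Config(data=data, provenance=provenance)
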