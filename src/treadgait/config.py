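"""YAML configuration for trials and sweeps.

Schema (all keys optional, defaults as in the dataclasses)::

    model:      {mass: 63.0, height: 1.73}
    treadmill:  {target_speed: 1.05, fmax: 300.0, fctrl: 17.0,
                 m_belt: 60.0, mu_deck: 0.05, mu: 0.9, ideal: false}
    controller: {kp: [...6], kd: [...6], tau_max: 250.0,
                 pitch_kp: 2000.0, pitch_kd: 200.0,
                 height_kp: 500.0, height_kd: 50.0,
                 weights: {wp: 0.65, wv: 0.1, we: 0.15, wc: 0.1},
                 stabilizer: true}
    experiment: {speed: 1.05, duration: 12.0, dt: 5.0e-4, seed: 0,
                 overground: true,
                 sweep: {fmax: [...], fctrl: [...], mass: [...], speed: [...]}}

``overground: true`` ignores the ``treadmill`` section for single trials.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import yaml

from .controller import PDGains, RewardWeights
from .experiments import TrialConfig
from .treadmill import TreadmillSpec


def load_config(path) -> tuple[TrialConfig, dict[str, list[float]] | None]:
    """Read a YAML config; returns (trial config, sweep grid or None)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = raw.get("model", {})
    ctrl = raw.get("controller", {})
    exp = raw.get("experiment", {})

    gains = PDGains()
    for key in ("tau_max", "pitch_kp", "pitch_kd", "height_kp", "height_kd"):
        if key in ctrl:
            setattr(gains, key, float(ctrl[key]))
    for key in ("kp", "kd"):
        if key in ctrl:
            arr = np.asarray(ctrl[key], dtype=float)
            if arr.shape != (6,):
                raise ValueError(f"controller.{key} must list 6 gains")
            setattr(gains, key, arr)
    weights = RewardWeights(**ctrl.get("weights", {}))

    treadmill = None
    if not exp.get("overground", True):
        treadmill = TreadmillSpec(**raw.get("treadmill", {"target_speed": 1.05}))

    config = TrialConfig(
        mass=float(model.get("mass", 63.0)),
        height=float(model.get("height", 1.73)),
        speed=float(exp.get("speed", 1.05)),
        treadmill=treadmill,
        duration=float(exp.get("duration", 12.0)),
        dt=float(exp.get("dt", 5e-4)),
        seed=int(exp.get("seed", 0)),
        gains=gains,
        weights=weights,
        stabilizer=bool(ctrl.get("stabilizer", True)),
    )
    sweep = exp.get("sweep")
    if sweep is not None:
        sweep = {k: [float(x) for x in v] for k, v in sweep.items()}
    return config, sweep


def save_config(config: TrialConfig, path, sweep: dict | None = None) -> None:
    """Write a YAML config reproducing ``config`` (and optional sweep)."""
    doc: dict = {
        "model": {"mass": config.mass, "height": config.height},
        "controller": {
            "kp": [float(x) for x in config.gains.kp],
            "kd": [float(x) for x in config.gains.kd],
            "tau_max": config.gains.tau_max,
            "pitch_kp": config.gains.pitch_kp,
            "pitch_kd": config.gains.pitch_kd,
            "height_kp": config.gains.height_kp,
            "height_kd": config.gains.height_kd,
            "weights": asdict(config.weights),
            "stabilizer": config.stabilizer,
        },
        "experiment": {
            "speed": config.speed,
            "duration": config.duration,
            "dt": config.dt,
            "seed": config.seed,
            "overground": config.treadmill is None,
        },
    }
    if config.treadmill is not None:
        doc["treadmill"] = {
            "target_speed": config.treadmill.target_speed,
            "fmax": config.treadmill.fmax,
            "fctrl": config.treadmill.fctrl,
            "m_belt": config.treadmill.m_belt,
            "mu_deck": config.treadmill.mu_deck,
            "mu": config.treadmill.mu,
            "ideal": config.treadmill.ideal,
        }
    if sweep is not None:
        doc["experiment"]["sweep"] = sweep
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
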