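"""Configuration schema, result serialisation and fixture generation.

A scenario config file (YAML or JSON) mirrors :class:`ScenarioConfig`:

    scenario:
      preset: nominal            # optional base, expanded first
      gains: fast_eradication    # preset name or {alpha,k1,k2,k3}
      x0: {x: 10000, y: 12000, z: 7000}
      horizon: 200
      order: {q: 0.98, step: 0.05}          # omit for integer order
      integrator: {method: rk4_fixed, step: 0.01}
      seed: 0
    reward:                      # optional, for tuning runs
      sigma1: 1.0
      sigma2: 10.0
      epsilon: 5.0

The schema is strict: unknown keys raise, so a misspelt parameter can
never silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .closed_loop import (PerturbationSpec, ScenarioConfig, SimulationMetrics,
                          SimulationResult, eradication_time_channel,
                          scenario_preset, settling_time_channel)
from .controller import ControlGains, ControllerMode, gain_preset
from .integrators import FractionalConfig, IntegratorConfig, Trajectory
from .model import ModelParams, SystemState

__all__ = [
    "ConfigError",
    "load_config",
    "scenario_to_dict",
    "scenario_from_dict",
    "write_result",
    "read_result",
    "generate_fixture",
    "RunManifest",
]

CSV_COLUMNS = ["t", "x", "y", "z", "u1", "u2", "e", "xstar", "V", "Vdot"]


class ConfigError(ValueError):
    """A config file violated the documented schema."""


def _build(cls, data: Mapping[str, Any], context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid {context}: {err}") from err


def scenario_from_dict(data: Mapping[str, Any]) -> ScenarioConfig:
    """Expand and validate a scenario mapping (strict schema)."""
    data = dict(data)
    base = scenario_preset(data.pop("preset")) if "preset" in data else ScenarioConfig()
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in scenario: {sorted(unknown)}")
    kw: dict[str, Any] = {}
    if "true_params" in data:
        kw["true_params"] = _build(ModelParams, data["true_params"],
                                   "scenario.true_params")
    if "nominal_params" in data and data["nominal_params"] is not None:
        kw["nominal_params"] = _build(ModelParams, data["nominal_params"],
                                      "scenario.nominal_params")
    if "gains" in data:
        g = data["gains"]
        kw["gains"] = gain_preset(g) if isinstance(g, str) \
            else _build(ControlGains, g, "scenario.gains")
    if "mode" in data:
        m = data["mode"]
        kw["mode"] = ControllerMode(variant=m) if isinstance(m, str) \
            else _build(ControllerMode, _mode_dict(m), "scenario.mode")
    if "x0" in data:
        kw["x0"] = _build(SystemState, data["x0"], "scenario.x0")
    if "order" in data and data["order"] is not None:
        kw["order"] = _build(FractionalConfig, data["order"], "scenario.order")
    if "integrator" in data:
        kw["integrator"] = _build(IntegratorConfig, data["integrator"],
                                  "scenario.integrator")
    for key in ("horizon", "measurement_interval", "seed"):
        if key in data:
            kw[key] = data[key]
    try:
        return dataclasses.replace(base, **kw)
    except ValueError as err:
        raise ConfigError(str(err)) from err


def _mode_dict(m: Mapping[str, Any]) -> dict[str, Any]:
    d = dict(m)
    if isinstance(d.get("nominal_params"), Mapping):
        d["nominal_params"] = _build(ModelParams, d["nominal_params"],
                                     "scenario.mode.nominal_params")
    return d


def scenario_to_dict(scenario: ScenarioConfig) -> dict[str, Any]:
    d = asdict(scenario)
    if d["mode"]["nominal_params"] is None:
        d["mode"].pop("nominal_params")
    if d["order"] is None:
        d.pop("order")
    if d["nominal_params"] is None:
        d.pop("nominal_params")
    return d


def load_config(path: str | Path):
    """Load a scenario (and optional reward) config file.

    Returns ``(ScenarioConfig, RewardConfig | None)``.  Unknown keys at
    any level are an error.
    """
    from .gain_tuning import RewardConfig

    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as err:
        raise ConfigError(f"{path}: cannot parse config: {err}") from err
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - {"scenario", "reward"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    if "scenario" not in data:
        raise ConfigError(f"{path}: missing required 'scenario' block")
    scenario = scenario_from_dict(data["scenario"])
    reward_cfg = None
    if "reward" in data and data["reward"] is not None:
        reward_cfg = _build(RewardConfig, data["reward"], "reward")
    return scenario, reward_cfg


# ---------------------------------------------------------------------------
# Results

def write_result(result: SimulationResult, path: str | Path) -> tuple[Path, Path]:
    """Write a run as CSV (column contract t,x,y,z,u1,u2,e,xstar,V,Vdot)
    plus a JSON metrics sidecar.  Returns (csv_path, json_path)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj = result.trajectory
    frame = {"t": traj.times}
    for col in ("x", "y", "z", "u1", "u2"):
        try:
            frame[col] = traj.channel(col)
        except KeyError:
            frame[col] = np.full(len(traj), np.nan)
    for col in ("e", "xstar", "V", "Vdot"):
        frame[col] = traj.diagnostics.get(col, np.full(len(traj), np.nan))
    df = pd.DataFrame(frame, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".metrics.json")
    payload = {
        "metrics": asdict(result.metrics),
        "scenario": scenario_to_dict(result.scenario),
        "version": __version__,
    }
    sidecar.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path, sidecar


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_result(csv_path: str | Path) -> tuple[Trajectory, dict[str, Any]]:
    """Read back a written run: (trajectory with channels, sidecar payload)."""
    csv_path = Path(csv_path)
    # round_trip parsing so that metrics recomputed from the CSV are
    # bit-identical to the stored ones
    df = pd.read_csv(csv_path, float_precision="round_trip")
    traj = Trajectory(df["t"].to_numpy(), df[["x", "y", "z"]].to_numpy())
    traj.inputs = df[["u1", "u2"]].to_numpy()
    for col in ("e", "xstar", "V", "Vdot"):
        traj.diagnostics[col] = df[col].to_numpy()
    sidecar = csv_path.with_suffix(csv_path.suffix + ".metrics.json")
    payload = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return traj, payload


def recompute_metrics(traj: Trajectory) -> dict[str, float | None]:
    """Metric recomputation from a (possibly re-read) trajectory; used to
    verify that stored metrics are reproducible from the CSV alone."""
    try:
        settle = settling_time_channel(traj.times, traj.channel("x"))
    except ValueError:
        settle = None
    return {
        "tumour_eradication_time": eradication_time_channel(
            traj.times, traj.channel("y"), 1.0),
        "il2_clearance_time": eradication_time_channel(
            traj.times, traj.channel("z"), 1.0),
        "u2_settling_to_zero_time": eradication_time_channel(
            traj.times, traj.channel("u2"), 1.0),
        "effector_settling_time": settle,
    }


# ---------------------------------------------------------------------------
# Fixtures

FIXTURE_KINDS = ("nominal", "perturbed", "fractional", "decay_only")


def generate_fixture(kind: str, seed: int = 0) -> ScenarioConfig:
    """Deterministic, seed-parameterised test scenarios.

    ``nominal``/``fractional`` mirror the named presets; ``perturbed``
    applies a random-sign 30% parameter mismatch between plant and
    controller; ``decay_only`` switches tumour growth off (r2 = 0) so
    that every channel has a closed-form reference.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    if kind == "nominal":
        return dataclasses.replace(scenario_preset("nominal"), seed=seed)
    if kind == "fractional":
        return dataclasses.replace(scenario_preset("fractional"), seed=seed)
    if kind == "perturbed":
        base = scenario_preset("nominal")
        rng = np.random.default_rng(seed)
        spec = PerturbationSpec(level=0.3, direction="random_sign")
        true = spec.apply(base.true_params, rng)
        return dataclasses.replace(base, true_params=true,
                                   nominal_params=base.true_params, seed=seed)
    base = scenario_preset("nominal")
    decay_params = base.true_params.scaled({"r2": 0.0})
    return dataclasses.replace(base, true_params=decay_params, horizon=40.0,
                               seed=seed)


# ---------------------------------------------------------------------------
# Run manifest

@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a CLI run exactly."""

    command: str
    config: dict[str, Any]
    seed: int
    outputs: tuple[str, ...]
    version: str = __version__
    started_at: float = 0.0

    @classmethod
    def create(cls, command: str, config: Mapping[str, Any], seed: int,
               outputs: tuple[str, ...]) -> "RunManifest":
        return cls(command=command, config=dict(config), seed=seed,
                   outputs=outputs, started_at=time.time())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_json_default)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        data = json.loads(text)
        data["outputs"] = tuple(data["outputs"])
        return cls(**data)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path
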