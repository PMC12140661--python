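"""Closed-loop experiments: plant + backstepping controller.

Wires the tumour-immune plant to the feedback law, propagates the loop
(integer-order or Caputo fractional), and extracts the performance
metrics used throughout: eradication times, IL-2 clearance, settling
time of the effector level, input peaks and boundedness diagnostics.

The controller always evaluates with the scenario's *nominal* parameter
set while the plant evolves under the *true* one; robustness sweeps
perturb the true parameters and leave the controller's belief fixed,
which realises parametric uncertainty as a bounded perturbation of the
error dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ModelParams, SystemState, default_params, rhs
from .controller import (ControlGains, ControllerMode, control_inputs,
                         costate_target, gain_preset, tracking_error)
from .integrators import (DivergenceError, FractionalConfig, IntegratorConfig,
                          Trajectory, integrate_caputo, integrate_ode)
from .stability import LyapunovConfig, lyapunov_rate_expected, lyapunov_value

__all__ = [
    "ScenarioConfig",
    "PerturbationSpec",
    "SimulationMetrics",
    "SimulationResult",
    "SCENARIO_PRESETS",
    "scenario_preset",
    "simulate",
    "eradication_time",
    "settling_time",
    "uncertainty_sweep",
]

#: Reference initial state: 1e4 effector cells, 1.2e4 tumour cells,
#: 7e3 IL-2 units.
DEFAULT_X0 = SystemState(x=10_000.0, y=12_000.0, z=7_000.0)

#: Default "reached zero" threshold in model units; a continuous model
#: never reaches exactly zero, so eradication is first passage below an
#: absolute threshold that is held for the rest of the horizon.
ZERO_THRESHOLD = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one closed-loop experiment."""

    true_params: ModelParams = field(default_factory=default_params)
    nominal_params: ModelParams | None = None    # defaults to true_params
    gains: ControlGains = field(default_factory=ControlGains)
    mode: ControllerMode = field(default_factory=ControllerMode)
    x0: SystemState = DEFAULT_X0
    horizon: float = 200.0                       # days
    order: FractionalConfig | None = None        # None = integer order
    measurement_interval: float | None = None    # None = continuous feedback
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.measurement_interval is not None and self.measurement_interval <= 0:
            raise ValueError("measurement interval must be positive")

    @property
    def controller_params(self) -> ModelParams:
        return self.nominal_params if self.nominal_params is not None \
            else self.true_params


#: Default uncertainty set: the tumour/effector kinetic parameters.  The
#: IL-2 pharmacology (p2, g3, mu3) is excluded by default because the
#: feedback cancels the production term p2*x*z/(g3+y) -- roughly 200*z at
#: the therapeutic operating point -- exactly; a relative error there
#: leaves a residual *proportional to z* with gain far above any
#: clinically sensible k3, so the loop diverges in every mismatch
#: direction and the bounded-perturbation premise of the BIBO analysis
#: is violated.  Those parameters must be calibrated, not swept.
KINETIC_PARAMS = ("c", "mu2", "p1", "g1", "g2", "r2", "b", "a")


@dataclass(frozen=True)
class PerturbationSpec:
    """Relative parameter deviation applied to the plant in a sweep.

    ``affected`` is the subset of parameter names to perturb; the
    default (None) resolves to :data:`KINETIC_PARAMS`.
    """

    level: float = 0.0                  # rho in [0, 1]
    direction: str = "inflate"          # inflate | deflate | random_sign
    affected: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("perturbation level must lie in [0, 1]")
        if self.direction not in ("inflate", "deflate", "random_sign"):
            raise ValueError(f"unknown perturbation direction {self.direction!r}")

    def apply(self, params: ModelParams, rng: np.random.Generator) -> ModelParams:
        names = self.affected if self.affected is not None else KINETIC_PARAMS
        if self.level == 0.0:
            return params
        if self.direction == "inflate":
            factors = {n: 1.0 + self.level for n in names}
        elif self.direction == "deflate":
            factors = {n: 1.0 - self.level for n in names}
        else:
            signs = rng.choice([-1.0, 1.0], size=len(names))
            factors = {n: 1.0 + s * self.level for n, s in zip(names, signs)}
        return params.scaled(factors)


@dataclass(frozen=True)
class SimulationMetrics:
    tumour_eradication_time: float | None
    il2_clearance_time: float | None
    u2_settling_to_zero_time: float | None
    effector_settling_time: float | None
    steady_state_x: float
    peak_u1: float
    peak_u2: float
    negative_states: tuple[str, ...]
    diverged: bool = False
    divergence_time: float | None = None


@dataclass
class SimulationResult:
    scenario: ScenarioConfig
    trajectory: Trajectory
    metrics: SimulationMetrics


# ---------------------------------------------------------------------------
# Scenario presets mirroring the reference experiments.

def _preset_configs() -> dict[str, ScenarioConfig]:
    return {
        # 200-day integer-order run whose analytic steady state is
        # x_ss = (g2/a)(r2 + k1) = 27000 effector cells.
        "nominal": ScenarioConfig(gains=gain_preset("steady_therapy"),
                                  horizon=200.0),
        # aggressive gains: tumour and u2 reach the zero threshold < 50 d.
        "fast": ScenarioConfig(gains=gain_preset("fast_eradication"),
                               horizon=100.0),
        # Caputo order q = 0.98, coarser grid to keep the O(N^2) memory
        # sums cheap over 150 days.
        "fractional": ScenarioConfig(gains=gain_preset("fast_eradication"),
                                     horizon=150.0,
                                     order=FractionalConfig(q=0.98, step=0.05)),
    }


SCENARIO_PRESETS = tuple(_preset_configs())


def scenario_preset(name: str) -> ScenarioConfig:
    presets = _preset_configs()
    try:
        return presets[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario preset {name!r}; known: {sorted(presets)}"
        ) from None


# ---------------------------------------------------------------------------
# Simulation

def _feedback_field(scenario: ScenarioConfig):
    plant = scenario.true_params
    ctrl = scenario.controller_params
    gains, mode = scenario.gains, scenario.mode

    def field_fn(t: float, X: np.ndarray) -> np.ndarray:
        x, y, z = X
        u1, u2 = control_inputs(x, y, z, ctrl, gains, mode)
        return np.array(rhs(x, y, z, plant, u1, u2))

    return field_fn


def _held_field(scenario: ScenarioConfig, u1: float, u2: float):
    plant = scenario.true_params

    def field_fn(t: float, X: np.ndarray) -> np.ndarray:
        x, y, z = X
        return np.array(rhs(x, y, z, plant, u1, u2))

    return field_fn


def _simulate_zoh(scenario: ScenarioConfig) -> tuple[Trajectory, np.ndarray]:
    """Zero-order-hold feedback: inputs computed at sample instants
    t_i = i * measurement_interval and held constant in between."""
    if scenario.order is not None:
        raise ValueError("zero-order-hold measurement is supported for the "
                         "integer-order loop only")
    dt = scenario.measurement_interval
    step = scenario.integrator.step
    n_sub = max(1, int(round(dt / step)))
    cfg = replace(scenario.integrator, method="rk4_fixed", step=dt / n_sub)
    ctrl, gains, mode = scenario.controller_params, scenario.gains, scenario.mode

    n_hold = int(math.ceil(scenario.horizon / dt))
    X = np.array(scenario.x0.as_tuple())
    times = [0.0]
    states = [X.copy()]
    inputs = []
    t = 0.0
    for i in range(n_hold):
        u1, u2 = control_inputs(X[0], X[1], X[2], ctrl, gains, mode)
        t_end = min((i + 1) * dt, scenario.horizon)
        seg = integrate_ode(_held_field(scenario, u1, u2), X, (t, t_end), cfg)
        times.extend(seg.times[1:])
        states.extend(seg.states[1:])
        inputs.extend([(u1, u2)] * (len(seg) - 1))
        X = seg.states[-1]
        t = t_end
    inputs.append(inputs[-1])  # input at the final instant: last held value
    traj = Trajectory(np.array(times), np.array(states))
    return traj, np.array(inputs)


def _diagnostics(traj: Trajectory, scenario: ScenarioConfig,
                 inputs: np.ndarray | None) -> None:
    """Populate input and diagnostic channels on a simulated trajectory."""
    ctrl = scenario.controller_params
    gains, mode = scenario.gains, scenario.mode
    x, y, z = traj.states.T
    if inputs is None:
        u = np.array([control_inputs(xi, yi, zi, ctrl, gains, mode)
                      for xi, yi, zi in zip(x, y, z)])
    else:
        u = inputs
    traj.inputs = u
    xstar = costate_target(y, ctrl, gains)
    e = gains.alpha * x - xstar
    cfg = LyapunovConfig(alpha=gains.alpha)
    traj.diagnostics["e"] = e
    traj.diagnostics["xstar"] = xstar
    traj.diagnostics["V"] = lyapunov_value(y, e, z, cfg)
    traj.diagnostics["Vdot"] = lyapunov_rate_expected(y, e, z, gains)


def _metrics(traj: Trajectory, scenario: ScenarioConfig,
             diverged: bool = False,
             divergence_time: float | None = None) -> SimulationMetrics:
    x = traj.channel("x")
    neg = tuple(name for name in ("x", "y", "z")
                if np.any(traj.channel(name) < 0.0))
    tail = max(1, int(0.05 * len(traj)))
    try:
        settle = settling_time_channel(traj.times, x)
    except ValueError:
        settle = None
    return SimulationMetrics(
        tumour_eradication_time=eradication_time_channel(
            traj.times, traj.channel("y"), ZERO_THRESHOLD),
        il2_clearance_time=eradication_time_channel(
            traj.times, traj.channel("z"), ZERO_THRESHOLD),
        u2_settling_to_zero_time=eradication_time_channel(
            traj.times, traj.channel("u2"), ZERO_THRESHOLD),
        effector_settling_time=settle,
        steady_state_x=float(np.mean(x[-tail:])),
        peak_u1=float(np.max(np.abs(traj.channel("u1")))),
        peak_u2=float(np.max(np.abs(traj.channel("u2")))),
        negative_states=neg,
        diverged=diverged,
        divergence_time=divergence_time,
    )


def simulate(scenario: ScenarioConfig) -> SimulationResult:
    """Run one closed-loop experiment and compute its metrics.

    Deterministic: an identical scenario (including seed) reproduces the
    result bit for bit.  Raises :class:`DivergenceError` if the state
    leaves the integrator's overflow bound.
    """
    scenario.mode.check_gains(scenario.gains)
    x0 = np.array(scenario.x0.as_tuple())
    inputs = None
    if scenario.measurement_interval is not None:
        traj, inputs = _simulate_zoh(scenario)
    elif scenario.order is not None:
        traj = integrate_caputo(_feedback_field(scenario), scenario.order.q,
                                x0, (0.0, scenario.horizon), scenario.order)
    else:
        traj = integrate_ode(_feedback_field(scenario), x0,
                             (0.0, scenario.horizon), scenario.integrator)
    _diagnostics(traj, scenario, inputs)
    return SimulationResult(scenario, traj, _metrics(traj, scenario))


# ---------------------------------------------------------------------------
# Metrics

def eradication_time_channel(times: np.ndarray, values: np.ndarray,
                             threshold: float) -> float | None:
    """First grid time at which |values| falls below ``threshold`` and
    stays below it for the rest of the horizon; None if never."""
    below = np.abs(values) < threshold
    if not below[-1]:
        return None
    # last index where the channel is NOT below the threshold
    above = np.nonzero(~below)[0]
    idx = 0 if len(above) == 0 else above[-1] + 1
    return float(times[idx])


def eradication_time(result: SimulationResult, species: str,
                     threshold: float = ZERO_THRESHOLD) -> float | None:
    """Sustained first-passage time of a channel below ``threshold``.

    ``species`` is one of x, y, z, u1, u2 (or a diagnostic channel).
    """
    traj = result.trajectory
    return eradication_time_channel(traj.times, traj.channel(species), threshold)


def settling_time_channel(times: np.ndarray, values: np.ndarray,
                          band: float = 0.02) -> float:
    """First time after which the channel stays within +/- band (relative)
    of its final value, the final value being the mean over the last 5%
    of the horizon.  Raises ``ValueError`` when the channel has not
    converged (last-5% spread exceeds the band)."""
    tail = max(2, int(0.05 * len(values)))
    final = float(np.mean(values[-tail:]))
    scale = abs(final) if final != 0.0 else 1.0
    spread = float(np.max(np.abs(values[-tail:] - final)))
    if spread > band * scale:
        raise ValueError(
            f"channel has not converged: last-5% spread {spread:.3g} exceeds "
            f"band {band * scale:.3g}")
    outside = np.nonzero(np.abs(values - final) > band * scale)[0]
    idx = 0 if len(outside) == 0 else outside[-1] + 1
    return float(times[idx])


def settling_time(result: SimulationResult, species: str,
                  band: float = 0.02) -> float:
    traj = result.trajectory
    return settling_time_channel(traj.times, traj.channel(species), band)


# ---------------------------------------------------------------------------
# Robustness sweeps

def uncertainty_sweep(base: ScenarioConfig, levels: list[float],
                      spec: PerturbationSpec = PerturbationSpec()
                      ) -> list[SimulationResult]:
    """Re-run ``base`` with the plant parameters perturbed at each level.

    The controller keeps the base scenario's (nominal) parameters; the
    plant uses the perturbed set, so the loop experiences a genuine
    model mismatch.  A diverging level is recorded (diverged flag with
    the partial trajectory absent) rather than aborting the sweep.
    """
    results: list[SimulationResult] = []
    nominal = base.controller_params
    for rho in levels:
        rng = np.random.default_rng(base.seed)
        level_spec = replace(spec, level=rho)
        perturbed = level_spec.apply(base.true_params, rng)
        scenario = replace(base, true_params=perturbed, nominal_params=nominal)
        try:
            results.append(simulate(scenario))
        except ValueError as verr:
            # leaving the admissible region (a Michaelis-Menten denominator
            # crossing zero) is recorded as a divergence event
            if "admissible" not in str(verr):
                raise
            results.append(_divergent_result(scenario, base,
                                             DivergenceError(float("nan"))))
        except DivergenceError as err:
            results.append(_divergent_result(scenario, base, err))
    return results


def _divergent_result(scenario: ScenarioConfig, base: ScenarioConfig,
                      err: DivergenceError) -> SimulationResult:
    t_end = err.t if np.isfinite(err.t) and err.t > 0 else 1e-9
    empty = Trajectory(np.array([0.0, t_end]),
                       np.array([base.x0.as_tuple(), base.x0.as_tuple()]))
    empty.inputs = np.zeros((2, 2))
    metrics = SimulationMetrics(None, None, None, None,
                                steady_state_x=float("nan"),
                                peak_u1=float("nan"),
                                peak_u2=float("nan"),
                                negative_states=(),
                                diverged=True, divergence_time=err.t)
    return SimulationResult(scenario, empty, metrics)
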