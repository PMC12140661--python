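"""Numerical propagation: integer-order ODEs and Caputo fractional systems.

The fractional solver is the Adams-Bashforth-Moulton predictor-corrector
on a uniform grid (Diethelm-type weights) with full memory: for the
Caputo initial-value problem D^q X = f(t, X), X(0) = X0, 0 < q <= 1,

    predictor:  X_{k+1}^P = X0 + h^q/Gamma(q+1) * sum_j b_{j,k+1} f_j
    corrector:  X_{k+1}   = X0 + h^q/Gamma(q+2)
                               * ( f(t_{k+1}, X^P) + sum_j a_{j,k+1} f_j )

with the standard product-rectangle / product-trapezoid weights.  At
q = 1 the scheme collapses to the classical one-step Adams pair and
matches the ODE integrators.  The memory sum is O(N) per step (O(N^2)
per trajectory), vectorised over the history.

A Mittag-Leffler evaluator E_q(s) = sum_n s^n / Gamma(q n + 1) is
provided as an independent oracle: linear Caputo relaxation
D^q z = -k z has the closed form z(t) = z0 * E_q(-k t^q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp

__all__ = [
    "IntegratorConfig",
    "FractionalConfig",
    "Trajectory",
    "DivergenceError",
    "integrate_ode",
    "integrate_caputo",
    "mittag_leffler",
]

Field = Callable[[float, np.ndarray], np.ndarray]


class DivergenceError(RuntimeError):
    """State magnitude exceeded the overflow bound during integration."""

    def __init__(self, t: float, message: str | None = None):
        self.t = t
        super().__init__(message or f"trajectory diverged at t = {t:.6g}")


@dataclass(frozen=True)
class IntegratorConfig:
    method: str = "rk4_fixed"            # or "rk45_adaptive"
    step: float = 0.01                   # days, fixed-step grid
    rel_tol: float = 1e-8
    abs_tol: float = 1e-8
    overflow: float = 1e15

    def __post_init__(self) -> None:
        if self.method not in ("rk4_fixed", "rk45_adaptive"):
            raise ValueError(f"unknown integrator method {self.method!r}")
        if self.step <= 0 or self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("step and tolerances must be positive")


@dataclass(frozen=True)
class FractionalConfig:
    q: float = 0.98                      # fractional order, 0 < q <= 1
    step: float = 0.05                   # days, uniform grid
    memory: int | None = None            # None = full history
    overflow: float = 1e15

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise ValueError("fractional order q must be in (0, 1]")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.memory is not None and self.memory < 1:
            raise ValueError("memory must be at least one step")


@dataclass
class Trajectory:
    """Uniformly sampled solution with input and diagnostic channels.

    ``states`` has shape (n, d); ``inputs`` (n, 2) when populated by the
    closed-loop layer.  ``diagnostics`` maps channel name (e, xstar, V,
    Vdot, ...) to an (n,) array.
    """

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray | None = None
    diagnostics: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.states):
            raise ValueError("times and states must have matching lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def channel(self, name: str) -> np.ndarray:
        """Return a named channel: a state column, input column or diagnostic."""
        cols = {"x": 0, "y": 1, "z": 2}
        if name in cols and self.states.shape[1] >= 3:
            return self.states[:, cols[name]]
        if name in ("u1", "u2"):
            if self.inputs is None:
                raise KeyError(f"channel {name!r}: trajectory has no inputs")
            return self.inputs[:, 0 if name == "u1" else 1]
        if name in self.diagnostics:
            return self.diagnostics[name]
        raise KeyError(f"unknown trajectory channel {name!r}")


def _check_overflow(t: float, x: np.ndarray, bound: float) -> None:
    if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > bound:
        raise DivergenceError(t)


def _grid(t_span: tuple[float, float], step: float) -> np.ndarray:
    t0, t1 = t_span
    if not t1 > t0:
        raise ValueError("t_span must be nondegenerate (t1 > t0)")
    n = int(round((t1 - t0) / step))
    n = max(n, 1)
    return t0 + step * np.arange(n + 1)


def integrate_ode(field_fn: Field, x0: Sequence[float],
                  t_span: tuple[float, float],
                  cfg: IntegratorConfig = IntegratorConfig()) -> Trajectory:
    """Propagate dX/dt = field_fn(t, X) over ``t_span``.

    ``rk4_fixed`` is the classical 4th-order Runge-Kutta on a uniform
    grid (the field -- and hence any embedded state feedback -- is
    re-evaluated at every stage); ``rk45_adaptive`` delegates to scipy's
    Dormand-Prince pair, sampled on the same uniform output grid.
    """
    x0 = np.asarray(x0, dtype=float)
    times = _grid(t_span, cfg.step)
    if cfg.method == "rk45_adaptive":
        sol = solve_ivp(field_fn, (times[0], times[-1]), x0, method="RK45",
                        t_eval=times, rtol=cfg.rel_tol, atol=cfg.abs_tol)
        if not sol.success:
            raise DivergenceError(float(sol.t[-1]) if len(sol.t) else times[0],
                                  sol.message)
        _check_overflow(times[-1], sol.y, cfg.overflow)
        return Trajectory(times, sol.y.T.copy())

    h = cfg.step
    out = np.empty((len(times), len(x0)))
    out[0] = x0
    x = x0
    for i, t in enumerate(times[:-1]):
        k1 = field_fn(t, x)
        k2 = field_fn(t + h / 2, x + (h / 2) * k1)
        k3 = field_fn(t + h / 2, x + (h / 2) * k2)
        k4 = field_fn(t + h, x + h * k3)
        x = x + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        _check_overflow(times[i + 1], x, cfg.overflow)
        out[i + 1] = x
    return Trajectory(times, out)


def integrate_caputo(field_fn: Field, q: float, x0: Sequence[float],
                     t_span: tuple[float, float],
                     cfg: FractionalConfig | None = None) -> Trajectory:
    """Propagate the Caputo system D^q X = field_fn(t, X), X(t0) = x0.

    Standard Caputo initial-value convention: integer-order initial
    condition at t0.  ``cfg.q`` is overridden by the explicit ``q``
    argument for convenience; ``cfg.memory`` truncates the history sum
    (full memory when None).
    """
    if cfg is None:
        cfg = FractionalConfig(q=q)
    if not 0.0 < q <= 1.0:
        raise ValueError("fractional order q must be in (0, 1]")
    x0 = np.asarray(x0, dtype=float)
    times = _grid(t_span, cfg.step)
    n_steps = len(times) - 1
    h = cfg.step
    d = len(x0)

    hq_g1 = h**q / math.gamma(q + 1.0)        # predictor scale
    hq_g2 = h**q / math.gamma(q + 2.0)        # corrector scale

    # Corrector weights a_{j,k+1} depend only on k-j for interior nodes:
    # a_interior(m) = (m+2)^{q+1} - 2(m+1)^{q+1} + m^{q+1}, m = k-j.
    m = np.arange(n_steps + 1, dtype=float)
    a_interior = (m + 2.0) ** (q + 1.0) - 2.0 * (m + 1.0) ** (q + 1.0) + m ** (q + 1.0)
    # Predictor weights b_{j,k+1} = (k+1-j)^q - (k-j)^q, i.e. b(m) with m = k-j.
    b_w = (m + 1.0) ** q - m ** q

    hist_f = np.empty((n_steps + 1, d))
    out = np.empty((n_steps + 1, d))
    out[0] = x0
    hist_f[0] = field_fn(times[0], x0)

    # Short-memory handling: nodes older than the window contribute through
    # accumulators frozen at their boundary weight.  At q = 1 all history
    # weights are m-independent (b = 1, interior a = 2, initial a = 1), so
    # freezing is exact and truncation cannot change the result; for q < 1
    # it is the usual short-memory approximation (weights decay ~ m^{q-1}).
    mem = cfg.memory
    tail_pred = np.zeros(d)
    tail_corr = np.zeros(d)

    for k in range(n_steps):
        t_next = times[k + 1]
        j0 = 0 if mem is None else max(0, k + 1 - mem)
        if mem is not None and j0 > 0:
            j_exp = j0 - 1  # exactly one node leaves the window per step
            m_exp = mem
            tail_pred += b_w[m_exp] * hist_f[j_exp]
            if j_exp == 0:
                a0 = k ** (q + 1.0) - (k - q) * (k + 1.0) ** q
                tail_corr += a0 * hist_f[0]
            else:
                tail_corr += a_interior[m_exp] * hist_f[j_exp]
        js = np.arange(j0, k + 1)
        fj = hist_f[j0:k + 1]
        # predictor (fractional Adams-Bashforth)
        pred = x0 + hq_g1 * (tail_pred + (b_w[k - js, None] * fj).sum(axis=0))
        # corrector: initial-node weight a_{0,k+1} = k^{q+1}-(k-q)(k+1)^q,
        # interior weights a_interior, terminal weight 1 on the predicted node.
        w = a_interior[k - js].copy()
        if j0 == 0:
            w[0] = k ** (q + 1.0) - (k - q) * (k + 1.0) ** q
        f_pred = field_fn(t_next, pred)
        x_next = x0 + hq_g2 * (f_pred + tail_corr + (w[:, None] * fj).sum(axis=0))
        _check_overflow(t_next, x_next, cfg.overflow)
        out[k + 1] = x_next
        hist_f[k + 1] = field_fn(t_next, x_next)
    return Trajectory(times, out)


# ---------------------------------------------------------------------------
# Mittag-Leffler oracle

_ML_ARG_MAX = 50.0


def _ml_series(q: float, s: float, tol: float = 1e-16) -> float:
    terms = []
    n = 0
    while True:
        term = s**n / math.gamma(q * n + 1.0)
        terms.append(term)
        if n > 2 and abs(term) < tol * max(1.0, abs(terms[0])):
            return math.fsum(terms)
        n += 1
        if n > 10_000:
            return math.fsum(terms)


def _ml_negative_integral(q: float, x: float) -> float:
    """E_q(-x) for x > 0, 0 < q < 1, via the spectral (complete-monotone)
    representation

        E_q(-t^q) = sin(q pi)/pi * int_0^inf r^{q-1} e^{-r t}
                    / (r^{2q} + 2 r^q cos(q pi) + 1) dr,  t = x^{1/q}.

    Robust for large x where the power series cancels catastrophically.
    """
    t = x ** (1.0 / q)
    cq = math.cos(q * math.pi)

    def integrand(r: float) -> float:
        rq = r**q
        return r ** (q - 1.0) * math.exp(-r * t) / (rq * rq + 2.0 * rq * cq + 1.0)

    # The denominator has a sharp minimum near r = 1 as q -> 1; split there.
    val = 0.0
    for lo, hi in ((0.0, 0.5), (0.5, 2.0), (2.0, np.inf)):
        part, _ = quad(integrand, lo, hi, limit=400, epsabs=1e-13, epsrel=1e-12)
        val += part
    return math.sin(q * math.pi) / math.pi * val


def mittag_leffler(q: float, arg: float) -> float:
    """One-parameter Mittag-Leffler function E_q(arg), 0 < q <= 1.

    E_1 is the exponential; for q < 1 and strongly negative arguments
    the power series is abandoned for a numerically stable integral
    representation.  Supported domain |arg| <= 50.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("order q must be in (0, 1]")
    if abs(arg) > _ML_ARG_MAX:
        raise ValueError(f"argument {arg} outside supported range |arg| <= {_ML_ARG_MAX}")
    if q == 1.0:
        return math.exp(arg)
    # the alternating series cancels catastrophically for strongly
    # negative arguments; switch to the integral representation early
    if arg >= -2.0:
        return _ml_series(q, arg)
    return _ml_negative_integral(q, -arg)
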