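"""Lyapunov machinery for the controlled error system.

On the error coordinates X = (y, e, z) the nominal closed loop satisfies

    V   = e^2/(2 alpha) + y^2/2 + z^2/2  =  X^T M X / 2,
    M   = diag(1, 1/alpha, 1),
    dV/dt = -k1 y^2 - k2 e^2 - k3 z^2  <=  0,

which yields the exponential envelope

    ||X(t)|| <= sqrt(lambda2/lambda1) ||X(0)|| exp(-gamma t / 2),

with gamma = min(k1, k2, k3) and lambda1/lambda2 the extreme eigenvalues
of M.  Under a bounded perturbation ||u_d|| <= delta (parameter
mismatch, disturbance), comparison-lemma analysis gives an ultimate
bound

    b = (lambda4 / lambda3) * sqrt(lambda2 / lambda1) * delta / theta,

where lambda3 bounds the quadratic decay (dV/dt <= -lambda3 ||X||^2 on
the nominal loop) and lambda4 the gradient (||dV/dX|| <= lambda4 ||X||);
theta in (0, 1) splits the decay between dominating the perturbation and
shrinking the ball.  Increasing any gain increases lambda3 and shrinks b.

The ``1/alpha`` weight is attached to the *error* component e, matching
the scalar definition of V (the matrix as printed elsewhere weights the
first component; we take the scalar form as authoritative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .controller import ControlGains
from .integrators import Trajectory

__all__ = [
    "LyapunovConfig",
    "StabilityReport",
    "lyapunov_value",
    "lyapunov_rate_expected",
    "lyapunov_eigenvalues",
    "verify_lyapunov_identity",
    "exponential_envelope",
    "ultimate_bound",
]


@dataclass(frozen=True)
class LyapunovConfig:
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be strictly positive")


@dataclass(frozen=True)
class StabilityReport:
    gamma: float                 # decay rate min(k1,k2,k3), 1/day
    lambda1: float               # min eigenvalue of M
    lambda2: float               # max eigenvalue of M
    lambda3: float               # quadratic-decay constant
    lambda4: float               # gradient bound
    theta: float | None = None
    delta: float | None = None
    ultimate: float | None = None
    envelope_violations: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 > self.lambda2:
            raise ValueError("lambda1 must not exceed lambda2")


def lyapunov_value(y: float, e: float, z: float,
                   cfg: LyapunovConfig = LyapunovConfig()) -> float:
    """V = e^2/(2 alpha) + y^2/2 + z^2/2 (vectorised over array inputs)."""
    return np.asarray(e) ** 2 / (2.0 * cfg.alpha) + np.asarray(y) ** 2 / 2.0 \
        + np.asarray(z) ** 2 / 2.0


def lyapunov_rate_expected(y: float, e: float, z: float,
                           gains: ControlGains) -> float:
    """Closed-loop rate dV/dt = -k1 y^2 - k2 e^2 - k3 z^2.

    Valid along the nominal loop at alpha = 1 (published law) and for
    any alpha under the general-alpha law, by construction.
    """
    return -(gains.k1 * np.asarray(y) ** 2 + gains.k2 * np.asarray(e) ** 2
             + gains.k3 * np.asarray(z) ** 2)


def lyapunov_eigenvalues(cfg: LyapunovConfig) -> tuple[float, float]:
    """(lambda1, lambda2): extreme eigenvalues of M = diag(1, 1/alpha, 1)."""
    w = 1.0 / cfg.alpha
    return min(1.0, w), max(1.0, w)


@dataclass(frozen=True)
class IdentityReport:
    """Outcome of the trajectory-level Lyapunov check."""

    n_points: int
    max_rel_error: float            # integer-order identity residual
    violations: list[float] = field(default_factory=list)
    monotone: bool | None = None    # fractional-mode nonincrease check

    @property
    def ok(self) -> bool:
        if self.monotone is not None:
            return self.monotone
        return not self.violations


def verify_lyapunov_identity(traj: Trajectory, gains: ControlGains,
                             cfg: LyapunovConfig = LyapunovConfig(),
                             tol: float = 1e-6,
                             fractional: bool = False) -> IdentityReport:
    """Check the Lyapunov decay along a simulated nominal trajectory.

    Integer-order runs: the centred finite difference of the recorded V
    channel must match the analytic rate -k1 y^2 - k2 e^2 - k3 z^2 within
    ``tol`` relative to the peak |dV/dt|.  Fractional runs: only monotone
    nonincrease of V is asserted (a pointwise check of the Caputo
    derivative of V would need a separate fractional-derivative
    estimator; the theory guarantees D^q V <= 0, which implies V
    nonincreasing).
    """
    t = traj.times
    y, e, z = traj.channel("y"), traj.channel("e"), traj.channel("z")
    V = lyapunov_value(y, e, z, cfg)
    if fractional:
        dV = np.diff(V)
        # tolerate numerical jitter at the level of rounding on V
        slack = 1e-9 * max(float(V.max()), 1.0)
        monotone = bool(np.all(dV <= slack))
        return IdentityReport(n_points=len(t), max_rel_error=float("nan"),
                              violations=[float(t[i + 1]) for i in
                                          np.nonzero(dV > slack)[0][:20]],
                              monotone=monotone)
    expected = lyapunov_rate_expected(y, e, z, gains)
    # 4th-order central differences on the uniform grid; the first/last
    # two points have no symmetric stencil and are excluded.
    h = float(t[1] - t[0])
    dV_num = (-V[4:] + 8.0 * V[3:-1] - 8.0 * V[1:-3] + V[:-4]) / (12.0 * h)
    scale = float(np.max(np.abs(expected)))
    scale = scale if scale > 0 else 1.0
    rel = np.abs(dV_num - expected[2:-2]) / scale
    bad = np.nonzero(rel > tol)[0] + 2
    return IdentityReport(n_points=len(t),
                          max_rel_error=float(rel.max()),
                          violations=[float(t[i]) for i in bad[:20]])


def exponential_envelope(x0_norm: float, gains: ControlGains,
                         cfg: LyapunovConfig = LyapunovConfig(),
                         t: float | np.ndarray = 0.0) -> float | np.ndarray:
    """Bound sqrt(lambda2/lambda1) * ||X(0)|| * exp(-gamma t / 2)."""
    lam1, lam2 = lyapunov_eigenvalues(cfg)
    gamma = min(gains.k1, gains.k2, gains.k3)
    return math.sqrt(lam2 / lam1) * x0_norm * np.exp(-0.5 * gamma * np.asarray(t))


def quadratic_bound_constants(gains: ControlGains,
                              cfg: LyapunovConfig = LyapunovConfig()
                              ) -> tuple[float, float]:
    """(lambda3, lambda4) for the perturbation analysis.

    dV/dt = -k1 y^2 - k2 e^2 - k3 z^2 <= -min(k) ||X||^2, so
    lambda3 = min(k1, k2, k3) independent of alpha; the gradient
    dV/dX = M X gives lambda4 = lambda2 (max eigenvalue of M), equal to
    1 at alpha = 1.
    """
    _, lam2 = lyapunov_eigenvalues(cfg)
    return min(gains.k1, gains.k2, gains.k3), lam2


def ultimate_bound(delta: float, theta: float, gains: ControlGains,
                   cfg: LyapunovConfig = LyapunovConfig()) -> float:
    """Ultimate bound b = (lambda4/lambda3) sqrt(lambda2/lambda1) delta/theta."""
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie strictly inside (0, 1)")
    if delta < 0:
        raise ValueError("perturbation bound delta must be nonnegative")
    lam1, lam2 = lyapunov_eigenvalues(cfg)
    lam3, lam4 = quadratic_bound_constants(gains, cfg)
    return (lam4 / lam3) * math.sqrt(lam2 / lam1) * delta / theta


def stability_report(gains: ControlGains,
                     cfg: LyapunovConfig = LyapunovConfig(),
                     theta: float | None = None,
                     delta: float | None = None,
                     envelope_violations: int = 0) -> StabilityReport:
    """Assemble the closed-form stability constants into a report."""
    lam1, lam2 = lyapunov_eigenvalues(cfg)
    lam3, lam4 = quadratic_bound_constants(gains, cfg)
    ult = None
    if theta is not None and delta is not None:
        ult = ultimate_bound(delta, theta, gains, cfg)
    return StabilityReport(gamma=min(gains.k1, gains.k2, gains.k3),
                           lambda1=lam1, lambda2=lam2,
                           lambda3=lam3, lambda4=lam4,
                           theta=theta, delta=delta, ultimate=ult,
                           envelope_violations=envelope_violations)
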