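"""Backstepping controller for the tumour-immune model.

Design idea (strict-feedback backstepping): the tumour equation

    dy/dt = r2*(1 - b*y)*y - a*x*y/(g2 + y)

has no direct input, but the effector level ``x`` multiplies the
clearance term, so a *costate target*

    x*(y) = (alpha/a) * (g2 + y) * (r2*(1 - b*y) + k1)

is designed such that if ``x`` tracks ``x*/alpha`` the tumour obeys
``dy/dt = -k1*y - (1/alpha)*(a*y/(g2+y))*e`` with tracking error
``e = alpha*x - x*``.  The inputs then feedback-linearise the remaining
channels:

    u1 cancels the effector dynamics so that e decays at rate ~k2,
    u2 cancels the IL-2 dynamics exactly:  dz/dt = -k3*z.

``x*`` expands to the quadratic polynomial A*y^2 + B*y + D with

    A = -alpha*r2*b/a
    B =  alpha*(r2 - r2*b*g2 + k1)/a
    D =  alpha*g2*(r2 + k1)/a

and its time derivative is taken analytically, dx*/dt = (2A*y + B)*dy/dt
-- exact cancellation, never numerical differentiation.

Controller variants
-------------------
``published``
    The published control law verbatim.  Its algebra is self-consistent
    only at ``alpha = 1`` (the printed tumour error dynamics and the
    Lyapunov cross-term cancellation both require it), so this variant
    hard-requires ``alpha = 1``.
``general_alpha``
    A re-derivation valid for any ``alpha > 0``: u1 is chosen so that
    de/dt = a*y^2/(g2+y) - alpha*k2*e, which together with the exact
    dy/dt above makes dV/dt = -k1*y^2 - k2*e^2 - k3*z^2 for the weighted
    Lyapunov function V = e^2/(2*alpha) + y^2/2 + z^2/2.  Coincides with
    ``published`` at alpha = 1.
``robust_nominal``
    The same law evaluated with the controller's *nominal* belief of the
    model parameters while the plant evolves under the true ones; the
    mismatch acts as a bounded perturbation on the error system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ModelParams, SystemState, ControlInput

__all__ = [
    "ControlGains",
    "CostateCoefficients",
    "ControllerMode",
    "GAIN_PRESETS",
    "gain_preset",
    "costate_coefficients",
    "costate_target",
    "tracking_error",
    "closed_loop_y_rate",
    "costate_rate",
    "control_law",
]

_VARIANTS = ("published", "general_alpha", "robust_nominal")


@dataclass(frozen=True)
class ControlGains:
    """Costate scaling ``alpha`` (dimensionless) and feedback gains (1/day)."""

    alpha: float = 1.0
    k1: float = 0.09
    k2: float = 1.0
    k3: float = 0.25

    def __post_init__(self) -> None:
        for name in ("alpha", "k1", "k2", "k3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"gain {name} must be strictly positive")


#: Reconstructed gain presets.  The published experiments do not print
#: their gains; these are pinned by the reported steady state
#: x_ss = (alpha/a)*g2*(r2 + k1) = 27000 (alpha=1, k1=0.09) and by the
#: reported eradication/clearance timings.
GAIN_PRESETS: dict[str, ControlGains] = {
    "steady_therapy": ControlGains(alpha=1.0, k1=0.09, k2=1.0, k3=0.25),
    "fast_eradication": ControlGains(alpha=1.0, k1=0.25, k2=1.0, k3=0.5),
}


def gain_preset(name: str) -> ControlGains:
    try:
        return GAIN_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown gain preset {name!r}; known: {sorted(GAIN_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class CostateCoefficients:
    """Coefficients of the quadratic costate polynomial x*(y) = A y^2 + B y + D."""

    A: float
    B: float
    D: float


@dataclass(frozen=True)
class ControllerMode:
    variant: str = "published"
    nominal_params: ModelParams | None = None
    #: clip negative inputs to zero (off: the design places no positivity
    #: constraint on the inputs)
    saturate_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"unknown controller variant {self.variant!r}; known: {_VARIANTS}"
            )

    def controller_params(self, true_params: ModelParams) -> ModelParams:
        """Parameters the control law evaluates with."""
        if self.variant == "robust_nominal" and self.nominal_params is not None:
            return self.nominal_params
        return true_params

    def check_gains(self, gains: ControlGains) -> None:
        if self.variant == "published" and gains.alpha != 1.0:
            raise ValueError(
                "published variant is only self-consistent at alpha = 1; "
                "use the general_alpha variant for other scalings"
            )


def costate_coefficients(params: ModelParams, gains: ControlGains) -> CostateCoefficients:
    """Expand the costate target into its polynomial coefficients."""
    al, a = gains.alpha, params.a
    A = -al * params.r2 * params.b / a
    B = al * (params.r2 - params.r2 * params.b * params.g2 + gains.k1) / a
    D = al * params.g2 * (params.r2 + gains.k1) / a
    return CostateCoefficients(A, B, D)


def costate_target(y: float, params: ModelParams, gains: ControlGains) -> float:
    """Desired (scaled) effector level x*(y) = (alpha/a)(g2+y)(r2(1-b y)+k1)."""
    return (gains.alpha / params.a) * (params.g2 + y) * (
        params.r2 * (1.0 - params.b * y) + gains.k1
    )


def tracking_error(x: float, y: float, params: ModelParams,
                   gains: ControlGains) -> float:
    """Backstepping error e = alpha*x - x*(y)."""
    return gains.alpha * x - costate_target(y, params, gains)


def closed_loop_y_rate(y: float, e: float, params: ModelParams,
                       gains: ControlGains, mode: ControllerMode) -> float:
    """Tumour rate dy/dt after substituting x = (e + x*)/alpha.

    ``general_alpha`` uses the exact substitution
    dy/dt = -k1*y - (1/alpha)*(a*y/(g2+y))*e; ``published`` keeps
    the published form with 1/alpha on both terms (identical at
    alpha = 1, which that variant requires anyway).
    """
    clearance = params.a * y / (params.g2 + y)
    if mode.variant == "general_alpha":
        return -gains.k1 * y - clearance * e / gains.alpha
    return (-gains.k1 * y - clearance * e) / gains.alpha


def costate_rate(y: float, e: float, params: ModelParams, gains: ControlGains,
                 mode: ControllerMode = ControllerMode()) -> float:
    """Analytic dx*/dt = (2A*y + B) * dy/dt along the closed loop."""
    coef = costate_coefficients(params, gains)
    return (2.0 * coef.A * y + coef.B) * closed_loop_y_rate(y, e, params, gains, mode)


def control_inputs(x: float, y: float, z: float, params: ModelParams,
                   gains: ControlGains,
                   mode: ControllerMode = ControllerMode()) -> tuple[float, float]:
    """Scalar fast path of :func:`control_law`.

    ``params`` here are the *plant* (true) parameters; in robust mode the
    law substitutes its nominal belief for every model parameter while
    the gains stay as designed.
    """
    mode.check_gains(gains)
    p = mode.controller_params(params)
    if p.g1 + z <= 0 or p.g2 + y <= 0 or p.g3 + y <= 0:
        raise ValueError("controller state outside admissible region")
    al = gains.alpha
    e = tracking_error(x, y, p, gains)
    xstar_dot = costate_rate(y, e, p, gains, mode)
    clearance = p.a * y / (p.g2 + y)
    # u1 linearises the e-channel: de/dt = alpha*(f1 + u1) - dx*/dt is
    # driven to a*y^2/(g2+y) - alpha*k2*e (general alpha); at alpha = 1
    # this reduces term-by-term to the published law.
    f1 = p.c * y - p.mu2 * x + p.p1 * x * z / (p.g1 + z)
    target_e_rate = clearance * y - al * gains.k2 * e
    u1 = (target_e_rate + xstar_dot) / al - f1
    # u2 linearises the z-channel exactly: dz/dt = -k3*z.
    u2 = -p.p2 * x * z / (p.g3 + y) + p.mu3 * z - gains.k3 * z
    if mode.saturate_at_zero:
        u1 = max(u1, 0.0)
        u2 = max(u2, 0.0)
    return u1, u2


def control_law(state: SystemState, params: ModelParams, gains: ControlGains,
                mode: ControllerMode = ControllerMode()) -> ControlInput:
    """Evaluate the backstepping feedback law at ``state``."""
    u1, u2 = control_inputs(state.x, state.y, state.z, params, gains, mode)
    return ControlInput(u1, u2)
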