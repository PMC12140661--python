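"""Kirschner-Panetta tumour-immune plant dynamics.

The model couples three concentrations: activated effector cells ``x``
(cytotoxic T-cells, NK cells, macrophages), tumour cells ``y``, and the
cytokine interleukin-2 ``z``.  Two treatment inputs act on the system:
``u1``, an external source of effector cells (e.g. LAK-cell infusion),
and ``u2``, an input of tumour-infiltrating lymphocytes feeding the IL-2
compartment.  Time is measured in days and concentrations in the model's
cell/IL-2 units.

The vector field is

    dx/dt = c*y - mu2*x + p1*x*z/(g1 + z) + u1
    dy/dt = r2*(1 - b*y)*y - a*x*y/(g2 + y)
    dz/dt = p2*x*z/(g3 + y) - mu3*z + u2

Tumour growth is logistic with rate ``r2`` and inverse carrying capacity
``b``; effector cells clear tumour cells through a Michaelis-Menten term
with half-saturation ``g2``; IL-2 drives effector proliferation (rate
``p1``, half-saturation ``g1``) and is produced by effector cells in
contact with tumour (rate ``p2``, half-saturation ``g3``) while decaying
at rate ``mu3``.  Antigenicity ``c`` recruits effectors in proportion to
tumour burden.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from typing import Mapping

__all__ = [
    "ModelParams",
    "SystemState",
    "ControlInput",
    "StateDerivative",
    "default_params",
    "vector_field",
]

#: Antigenicity is only constrained to a range in the source model.
C_MAX = 0.05


@dataclass(frozen=True)
class ModelParams:
    """The eleven rate constants of the tumour-immune model.

    Units: rates in 1/day, ``g1``/``g2``/``g3`` are half-saturation
    constants in IL-2/cell units, ``b`` is an inverse carrying capacity
    (1/cells).
    """

    c: float = C_MAX          # antigenicity, 0 <= c <= 0.05
    mu2: float = 0.03         # effector-cell death rate
    p1: float = 0.1245        # effector proliferation rate (IL-2 driven)
    g1: float = 2e7           # half-sat for proliferation
    g2: float = 1e5           # half-sat for cancer clearance
    r2: float = 0.18          # tumour growth rate
    b: float = 1e-9           # inverse tumour carrying capacity
    a: float = 1.0            # cancer clearance rate
    mu3: float = 10.0         # IL-2 decay rate
    p2: float = 5.0           # IL-2 production rate
    g3: float = 1e3           # half-sat of IL-2 production

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= C_MAX:
            raise ValueError(f"antigenicity c={self.c} outside [0, {C_MAX}]")
        for name in ("mu2", "p1", "g1", "g2", "a", "mu3", "p2", "g3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        # r2 = 0 switches tumour growth off (pure-clearance test scenarios)
        if self.r2 < 0:
            raise ValueError("growth rate r2 must be nonnegative")
        if self.b <= 0:
            raise ValueError("inverse carrying capacity b must be strictly positive")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**data)

    def scaled(self, factors: Mapping[str, float]) -> "ModelParams":
        """Return a copy with selected parameters multiplied by ``factors``.

        ``c`` is clipped back into its admissible range so that an
        inflated parameter set remains a valid model.
        """
        d = self.to_dict()
        for name, f in factors.items():
            if name not in d:
                raise ValueError(f"unknown model parameter: {name}")
            d[name] = d[name] * f
        d["c"] = min(max(d["c"], 0.0), C_MAX)
        return ModelParams(**d)


@dataclass(frozen=True)
class SystemState:
    """Concentrations (x: effector cells, y: tumour cells, z: IL-2)."""

    x: float
    y: float
    z: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class ControlInput:
    """Treatment inputs (u1: effector-cell source, u2: TIL/IL-2 input)."""

    u1: float = 0.0
    u2: float = 0.0

    def as_tuple(self) -> tuple[float, float]:
        return (self.u1, self.u2)


@dataclass(frozen=True)
class StateDerivative:
    """Time derivatives (integer or Caputo) of the state, per day."""

    dx: float
    dy: float
    dz: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


def default_params() -> ModelParams:
    """The standard parameterisation of the model.

    Antigenicity defaults to the upper end of its admissible range
    (c = 0.05), the conventional stress case; any value in [0, 0.05]
    may be configured.
    """
    return ModelParams()


def _check_denominators(y: float, z: float, p: ModelParams) -> None:
    if p.g1 + z <= 0 or p.g2 + y <= 0 or p.g3 + y <= 0:
        raise ValueError(
            "state outside admissible region: a Michaelis-Menten denominator "
            f"is non-positive (y={y}, z={z})"
        )


def rhs(x: float, y: float, z: float, p: ModelParams,
        u1: float = 0.0, u2: float = 0.0) -> tuple[float, float, float]:
    """Scalar fast path of :func:`vector_field` (no dataclass wrapping)."""
    _check_denominators(y, z, p)
    dx = p.c * y - p.mu2 * x + p.p1 * x * z / (p.g1 + z) + u1
    dy = p.r2 * (1.0 - p.b * y) * y - p.a * x * y / (p.g2 + y)
    dz = p.p2 * x * z / (p.g3 + y) - p.mu3 * z + u2
    return dx, dy, dz


def vector_field(state: SystemState, params: ModelParams,
                 inp: ControlInput = ControlInput()) -> StateDerivative:
    """Evaluate the plant dynamics at ``state`` under input ``inp``.

    Raises ``ValueError`` when any Michaelis-Menten denominator is
    non-positive (the state has left the admissible region).  Negative
    states are otherwise evaluated as-is; physical plausibility is a
    diagnostic concern of the closed-loop layer, not a constraint here.
    """
    dx, dy, dz = rhs(state.x, state.y, state.z, params, inp.u1, inp.u2)
    return StateDerivative(dx, dy, dz)
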