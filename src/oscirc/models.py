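"""Nondimensional ODE families for two-gene activator-repressor oscillators.

The circuit is a relaxation oscillator: an activator A drives its own gene
and the repressor gene R, and R feeds back negatively on A.  How the
negative feedback is implemented at the activator promoter distinguishes
the designs:

* **Design I** (competition): A and R bind mutually exclusively, so the two
  occupancy terms are *summed* in the regulation denominator.
* **Design II** (post-translational): R does not touch the promoter but
  catalyses degradation of A.
* **Design III** (non-competition): each factor has its own site; the
  occupancy factors *multiply*, which expands the denominator by a
  sigma*x^n*y^m cross term relative to Design I.

With x, y the activator/repressor concentrations scaled by their DNA-binding
constants, tau = t*delta_R, and Delta = delta_A/delta_R, the rate laws are

    dx/dtau = Delta * [ beta * f(x, y) - x * L(y) ]
    dy/dtau = Delta * gamma * g(x) - y

    Design I:   f = (1+alpha x^2)/(1+x^2+sigma y^2),          L = 1
    Design II:  f = (1+alpha x^2)/(1+x^2),                    L = 1+sigma' y
    Design III: f = (1+alpha x^2)/[(1+x^2)(1+sigma y^2)],     L = 1
    shared      g = (1+alpha x^n)/(1+x^n)

beta and gamma absorb transcription/translation strength scaled by the
*activator's* degradation rate, which is why Delta multiplies both
production terms; this is what places the repressor nullcline at
y = Delta*gamma*g(x) and makes Delta a genuine control parameter for the
bifurcation structure while x remains the fast variable for Delta >> 1.

Three further families reuse the same machinery: the generalized
non-competitive model (Design III with free Hill exponents n, m), the
effective Atkinson competition model (Design I with n = m = 4, two DNA
loops of paired dimers), and the Smolen circuit, in which *both* genes read
one competitively regulated promoter (monomer repressor by default), i.e.
g = (1+alpha x^n)/(1+x^n+sigma y^m).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import _kernels


class Design(Enum):
    """The six model families, with the kernel code implementing each."""

    DESIGN_I = ("DESIGN_I", _kernels.DESIGN_I)
    DESIGN_II = ("DESIGN_II", _kernels.DESIGN_II)
    DESIGN_III = ("DESIGN_III", _kernels.DESIGN_III)
    GENERALIZED_III = ("GENERALIZED_III", _kernels.DESIGN_III)
    ATKINSON_COMP = ("ATKINSON_COMP", _kernels.DESIGN_I)
    SMOLEN = ("SMOLEN", _kernels.SMOLEN)

    def __init__(self, label: str, code: int):
        self.label = label
        self.code = code


# designs whose Hill exponents are structurally fixed
_FIXED_EXPONENTS = {
    Design.DESIGN_I: (2, 2),
    Design.DESIGN_II: (2, 2),
    Design.DESIGN_III: (2, 2),
    Design.ATKINSON_COMP: (4, 4),
}


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional parameter set shared by all families.

    alpha : fold-activation of the bound vs basal promoter (> 1 expected)
    beta, gamma : transcription-translation strengths of activator/repressor
    sigma : repressor-to-activator DNA-binding ratio
    sigma_prime : repressor-catalysed degradation strength (Design II only)
    delta_ratio : Delta = delta_A/delta_R (> 0)
    n, m : activator / repressor multimerisation (Hill) exponents, integers
    """

    alpha: float = 50.0
    beta: float = 1.0
    gamma: float = 0.05
    sigma: float = 1.0
    sigma_prime: float = 0.0
    delta_ratio: float = 10.0
    n: int = 2
    m: int = 2

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "sigma", "sigma_prime", "delta_ratio"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v!r}")
        if self.delta_ratio <= 0:
            raise ValueError("delta_ratio must be positive")
        for name in ("n", "m"):
            v = getattr(self, name)
            if not float(v).is_integer():
                raise ValueError(f"Hill exponent {name} must be an integer, got {v!r}")
            if int(v) < 1:
                raise ValueError(f"Hill exponent {name} must be >= 1, got {v!r}")
            object.__setattr__(self, name, int(v))


@dataclass(frozen=True)
class StateVector:
    """Nondimensional state (x = activator, y = repressor, tau = t*delta_R)."""

    x: float
    y: float
    tau: float = 0.0


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional degradation rates; everything else is absorbed in beta/gamma."""

    delta_A: float  # activator degradation rate, per hour
    delta_R: float  # repressor degradation rate, per hour

    def __post_init__(self):
        if self.delta_A <= 0 or self.delta_R <= 0:
            raise ValueError("degradation rates must be positive")

    @property
    def delta_ratio(self) -> float:
        return self.delta_A / self.delta_R


@dataclass(frozen=True)
class ModelSpec:
    """A design bound to a parameter set; exposes rate law and Jacobian."""

    design: Design
    params: ModelParams

    # -- evaluation ---------------------------------------------------------
    @property
    def code(self) -> int:
        return self.design.code

    @property
    def pvec(self) -> np.ndarray:
        p = self.params
        return np.array([p.alpha, p.beta, p.gamma, p.sigma, p.sigma_prime,
                         p.delta_ratio, float(p.n), float(p.m)])

    def rhs(self, x: float, y: float) -> tuple[float, float]:
        if x < 0 or y < 0:
            raise ValueError(f"state must be nonnegative, got ({x}, {y})")
        return _kernels.rhs(self.code, float(x), float(y), self.pvec)

    def jac(self, x: float, y: float) -> np.ndarray:
        if x < 0 or y < 0:
            raise ValueError(f"state must be nonnegative, got ({x}, {y})")
        return _kernels.jacobian(self.code, float(x), float(y), self.pvec)

    # -- nullclines ---------------------------------------------------------
    def _g(self, x: np.ndarray) -> np.ndarray:
        """Shared activator-occupancy factor (1+alpha x^n)/(1+x^n)."""
        p = self.params
        xn = np.asarray(x, float) ** p.n
        return (1.0 + p.alpha * xn) / (1.0 + xn)

    def y_nullcline(self, x: np.ndarray) -> np.ndarray:
        """y on dy/dtau = 0; the repressor law shared by all designs."""
        p = self.params
        x = np.asarray(x, float)
        if self.design is not Design.SMOLEN:
            return p.delta_ratio * p.gamma * self._g(x)
        # Smolen: y*(1+x^n+sigma*y^m) = Delta*gamma*(1+alpha*x^n)
        xn = x ** p.n
        B = 1.0 + xn
        N = p.delta_ratio * p.gamma * (1.0 + p.alpha * xn)
        if p.m == 1:
            return (-B + np.sqrt(B * B + 4.0 * p.sigma * N)) / (2.0 * p.sigma)
        out = np.empty_like(B)
        for i in range(B.size):
            f = lambda y: y * (B.flat[i] + p.sigma * y ** p.m) - N.flat[i]
            hi = max(1.0, N.flat[i])
            while f(hi) < 0:
                hi *= 2
            out.flat[i] = brentq(f, 0.0, hi, xtol=1e-14)
        return out

    def x_nullcline(self, x: np.ndarray) -> np.ndarray:
        """y on dx/dtau = 0 (NaN where no nonnegative solution exists)."""
        p = self.params
        x = np.asarray(x, float)
        xn = x ** p.n
        B = 1.0 + xn
        N = 1.0 + p.alpha * xn
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.design in (Design.DESIGN_I, Design.ATKINSON_COMP, Design.SMOLEN):
                ym = (p.beta * N / x - B) / p.sigma
            elif self.design in (Design.DESIGN_III, Design.GENERALIZED_III):
                ym = (p.beta * (N / B) / x - 1.0) / p.sigma
            else:  # DESIGN_II, linear in y
                ym = (p.beta * (N / B) / x - 1.0) / p.sigma_prime
            ym = np.where(ym >= 0, ym, np.nan)
            if self.design is Design.DESIGN_II:
                return ym
            return ym ** (1.0 / p.m)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"design": self.design.label, "params": asdict(self.params)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return make_model(d["design"], **d["params"])

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


def make_model(design: Design | str, params: ModelParams | None = None, **kw) -> ModelSpec:
    """Build a :class:`ModelSpec`, enforcing design-specific requirements.

    Parameters may be given as a :class:`ModelParams` or as keyword
    overrides of its defaults (``alpha=50, delta_ratio=10, sigma=1, ...``).
    """
    if isinstance(design, str):
        try:
            design = Design[design]
        except KeyError:
            raise ValueError(f"unknown design id {design!r}") from None
    if not isinstance(design, Design):
        raise ValueError(f"unknown design id {design!r}")
    if params is None:
        defaults = {}
        if design is Design.SMOLEN:
            defaults = {"n": 2, "m": 1}
        if design in _FIXED_EXPONENTS:
            nm = _FIXED_EXPONENTS[design]
            defaults = {"n": nm[0], "m": nm[1]}
        params = ModelParams(**{**defaults, **kw})
    elif kw:
        raise TypeError("pass either a ModelParams or keyword overrides, not both")
    if design in _FIXED_EXPONENTS:
        n_req, m_req = _FIXED_EXPONENTS[design]
        if (params.n, params.m) != (n_req, m_req):
            raise ValueError(
                f"{design.label} is structurally fixed at n={n_req}, m={m_req}; "
                f"got n={params.n}, m={params.m}")
    if design is not Design.DESIGN_II and params.sigma_prime != 0.0:
        raise ValueError(f"sigma_prime is a Design II parameter; not valid for {design.label}")
    return ModelSpec(design=design, params=params)


def evaluate_rhs(model: ModelSpec, state: StateVector | Sequence[float]) -> tuple[float, float]:
    """(dx/dtau, dy/dtau) at one state."""
    x, y = (state.x, state.y) if isinstance(state, StateVector) else (state[0], state[1])
    return model.rhs(x, y)


def evaluate_jacobian(model: ModelSpec, state: StateVector | Sequence[float]) -> np.ndarray:
    """Analytic 2x2 Jacobian at one state."""
    x, y = (state.x, state.y) if isinstance(state, StateVector) else (state[0], state[1])
    return model.jac(x, y)


def nullclines(model: ModelSpec, x_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(y_x, y_y) curves on an ordered positive x grid.

    ``y_x`` solves dx/dtau = 0 for y at each x (NaN where no nonnegative
    solution); ``y_y`` solves dy/dtau = 0.  Fixed points sit at their
    intersections.
    """
    x_grid = np.asarray(x_grid, float)
    if x_grid.size == 0:
        raise ValueError("empty x grid")
    if np.any(x_grid <= 0) or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x grid must be positive and strictly increasing")
    return model.x_nullcline(x_grid), model.y_nullcline(x_grid)


def to_hours(period_nondim: float, delta_R: float) -> float:
    """Convert a period in units of 1/delta_R to hours (delta_R in 1/h)."""
    if delta_R <= 0:
        raise ValueError("delta_R must be positive")
    return period_nondim / delta_R
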