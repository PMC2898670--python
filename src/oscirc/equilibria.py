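"""Fixed points, eigenvalue stability, and damped-oscillation onsets.

A fixed point of the planar vector field is classified from its Jacobian
eigenvalues: a complex pair with negative real part marks *damped*
oscillations (stable focus), a positive real part marks a sustained-
oscillation candidate (the cycle itself is confirmed dynamically), and a
real eigenvalue pair gives nodes/saddles.  Complexification of the
eigenvalues along a parameter scan is the onset of the damped band
("gray area") that flanks every Hopf bifurcation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, root

from .models import Design, ModelParams, ModelSpec, make_model

RESIDUAL_TOL = 1e-9
MERGE_TOL = 1e-6

STABLE_NODE = "stable-node"
STABLE_FOCUS = "stable-focus"
UNSTABLE_NODE = "unstable-node"
UNSTABLE_FOCUS = "unstable-focus"
SADDLE = "saddle"


class NotAnEquilibriumError(ValueError):
    pass


@dataclass(frozen=True)
class FixedPointRecord:
    x_star: float
    y_star: float
    eigenvalues: tuple[complex, complex]
    stability: str
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability in (STABLE_NODE, STABLE_FOCUS)

    @property
    def is_focus(self) -> bool:
        return self.stability in (STABLE_FOCUS, UNSTABLE_FOCUS)


def _classify_eigs(w: np.ndarray) -> str:
    if abs(w[0].imag) > 1e-9:
        return STABLE_FOCUS if w[0].real < 0 else UNSTABLE_FOCUS
    re = np.sort(w.real)
    if re[0] < 0 < re[1]:
        return SADDLE
    return STABLE_NODE if re[1] < 0 else UNSTABLE_NODE


def _record(model, x: float, y: float) -> FixedPointRecord:
    fx, fy = model.rhs(x, y)
    res = float(np.hypot(fx, fy))
    w = np.linalg.eigvals(model.jac(x, y))
    return FixedPointRecord(x, y, (complex(w[0]), complex(w[1])), _classify_eigs(w), res)


def _polish(model, x0: float, y0: float) -> tuple[float, float] | None:
    """Newton-polish a candidate equilibrium using the analytic Jacobian."""
    if hasattr(model, "pvec"):  # gene-circuit models live in the closed quadrant
        clamp = lambda s: (max(s[0], 0.0), max(s[1], 0.0))
    else:
        clamp = lambda s: (s[0], s[1])
    sol = root(lambda s: model.rhs(*clamp(s)), [x0, y0],
               jac=lambda s: model.jac(*clamp(s)), method="hybr", tol=1e-13)
    x, y = clamp(sol.x)
    fx, fy = model.rhs(x, y)
    if np.hypot(fx, fy) < RESIDUAL_TOL:
        return x, y
    return None


def find_fixed_points(model, search_box=None,
                      grid_density: int = 400) -> list[FixedPointRecord]:
    """All equilibria in the box, residual < 1e-9, merged at 1e-6 separation.

    For the gene-circuit models the repressor nullcline y_y(x) is known in
    closed form, so roots are bracketed on the 1-D reduction
    F(x) = dx/dtau(x, y_y(x)) over a log-spaced grid (this cannot lose the
    three-crossing multistable cases).  Generic planar models (anything
    exposing only ``rhs``/``jac``) fall back to multi-start Newton seeded
    from a regular grid over the box.
    """
    if grid_density < 16:
        raise ValueError("grid_density must be >= 16")
    if search_box is None:
        if hasattr(model, "params"):
            # production is bounded: x* <= alpha*beta, y* <= Delta*gamma*alpha
            p = model.params
            search_box = ((1e-8, 10.0 * max(1.0, p.alpha * p.beta)),
                          (0.0, 10.0 * max(1.0, p.delta_ratio * p.gamma * p.alpha)))
        else:
            search_box = ((1e-8, 1e3), (0.0, 1e3))
    (xlo, xhi), (ylo, yhi) = search_box
    if xhi <= xlo or yhi < ylo:
        raise ValueError("search box must have positive extent")
    cands: list[tuple[float, float]] = []
    if hasattr(model, "y_nullcline"):
        xs = np.logspace(np.log10(max(xlo, 1e-12)), np.log10(xhi), grid_density * 10)
        yy = model.y_nullcline(xs)
        if hasattr(model, "pvec"):
            from ._kernels import rhs_x_array
            F = rhs_x_array(model.code, model.pvec, xs, np.asarray(yy, float))
        else:
            F = np.array([model.rhs(x, y)[0] for x, y in zip(xs, yy)])
        # x = 0 can be an equilibrium only when beta = 0
        if abs(model.rhs(0.0, float(model.y_nullcline(np.array([0.0]))[0]))[0]) < RESIDUAL_TOL:
            cands.append((0.0, float(model.y_nullcline(np.array([0.0]))[0])))
        sign = np.sign(F)
        for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
            xr = brentq(lambda x: model.rhs(x, float(model.y_nullcline(np.array([x]))[0]))[0],
                        xs[i], xs[i + 1], xtol=1e-14, rtol=8.9e-16)
            cands.append((xr, float(model.y_nullcline(np.array([xr]))[0])))
    else:
        gx = np.linspace(xlo, xhi, grid_density)
        gy = np.linspace(ylo, yhi, grid_density)
        norms = np.array([[np.hypot(*model.rhs(x, y)) for y in gy] for x in gx])
        order = np.argsort(norms, axis=None)
        for flat in order[: grid_density]:
            i, j = np.unravel_index(flat, norms.shape)
            cands.append((gx[i], gy[j]))
    out: list[FixedPointRecord] = []
    for x0, y0 in cands:
        p = _polish(model, x0, y0)
        if p is None:
            continue
        x, y = p
        if not (xlo - MERGE_TOL <= x <= xhi and ylo - MERGE_TOL <= y <= yhi):
            continue
        if any(np.hypot(x - r.x_star, y - r.y_star) < MERGE_TOL for r in out):
            continue
        out.append(_record(model, x, y))
    out.sort(key=lambda r: r.x_star)
    return out


def classify_fixed_point(model, point: Sequence[float]) -> FixedPointRecord:
    """Refine a near-equilibrium to residual < 1e-9 and classify it."""
    x0, y0 = float(point[0]), float(point[1])
    fx, fy = model.rhs(x0, y0)
    if np.hypot(fx, fy) > 1e-6 * (1 + abs(x0) + abs(y0)):
        raise NotAnEquilibriumError(f"residual {np.hypot(fx, fy):.2e} too large at {point}")
    p = _polish(model, x0, y0)
    if p is None:
        raise NotAnEquilibriumError(f"failed to refine candidate equilibrium {point}")
    return _record(model, *p)


def stable_points(model, **kw) -> list[FixedPointRecord]:
    return [r for r in find_fixed_points(model, **kw) if r.is_stable]


def _with_control(design: Design | str, control: str, value: float,
                  fixed: ModelParams) -> ModelSpec:
    return make_model(design, dataclasses.replace(fixed, **{control: value}))


class ConflictingStabilityError(RuntimeError):
    """Multiple coexisting stable equilibria disagree on focus/node character."""


def _damped_state(model, search_box=None) -> str:
    """'complex' / 'real' for the stable fixed point(s), 'none' if there is none."""
    stab = stable_points(model, search_box=search_box)
    if not stab:
        return "none"
    kinds = {r.stability for r in stab}
    if len(kinds) > 1:
        raise ConflictingStabilityError(
            f"coexisting stable equilibria with classes {sorted(kinds)}")
    return "complex" if kinds == {STABLE_FOCUS} else "real"


def damped_onset(design: Design | str, control: str, lo: float, hi: float,
                 fixed: ModelParams, n_scan: int = 200,
                 rel_tol: float = 1e-4) -> float | None:
    """Smallest control value at which the stable fixed point's eigenvalues
    acquire a nonzero imaginary part, bisected to ``rel_tol`` relative.

    Returns None if the eigenvalues stay real (or no transition into a
    stable focus occurs) over the range.  A transition from "no stable
    fixed point" directly into a stable focus — the Hopf boundary of an
    oscillatory band — counts as an onset: the damped band begins there.
    """
    if control not in ("beta", "gamma", "delta_ratio", "alpha", "sigma", "sigma_prime"):
        raise ValueError(f"unsupported control parameter {control!r}")
    if lo <= 0 or hi <= lo:
        raise ValueError("range must be positive and increasing")
    grid = np.geomspace(lo, hi, n_scan)
    states = [_damped_state(_with_control(design, control, v, fixed)) for v in grid]
    for i in range(len(grid) - 1):
        if states[i] != "complex" and states[i + 1] == "complex":
            a, b = grid[i], grid[i + 1]
            while (b - a) / b > rel_tol:
                mid = 0.5 * (a + b)
                if _damped_state(_with_control(design, control, mid, fixed)) == "complex":
                    b = mid
                else:
                    a = mid
            return 0.5 * (a + b)
    return None


NO_OSC = "no-oscillation"
DAMPED = "damped"
SUSTAINED_CANDIDATE = "sustained-candidate"


def cell_stability(model) -> tuple[str, float, float]:
    """(label, max Re lambda, |Im lambda|) for one parameter-space cell."""
    recs = find_fixed_points(model)
    if not recs:
        return SUSTAINED_CANDIDATE, np.nan, np.nan
    stab = [r for r in recs if r.is_stable]
    if not stab:
        # pick the non-saddle unstable point as the cycle's organising centre
        foci = [r for r in recs if r.stability in (UNSTABLE_FOCUS, UNSTABLE_NODE)]
        r = foci[0] if foci else recs[0]
        w = r.eigenvalues
        return SUSTAINED_CANDIDATE, max(c.real for c in w), abs(w[0].imag)
    r = next((s for s in stab if s.stability == STABLE_FOCUS), stab[0])
    w = r.eigenvalues
    label = DAMPED if r.stability == STABLE_FOCUS else NO_OSC
    return label, max(c.real for c in w), abs(w[0].imag)


def stability_map(design: Design | str, plane: tuple[str, str],
                  grid1: np.ndarray, grid2: np.ndarray,
                  fixed: ModelParams) -> "np.recarray":
    """Per-cell eigenvalue stability class over a 2-D parameter plane."""
    rows = []
    for v1, v2 in product(np.asarray(grid1, float), np.asarray(grid2, float)):
        params = dataclasses.replace(fixed, **{plane[0]: v1, plane[1]: v2})
        model = make_model(design, params)
        label, re_max, im = cell_stability(model)
        rows.append((v1, v2, label, re_max, im))
    return np.rec.fromrecords(
        rows, names=["p1", "p2", "klass", "re_lambda_max", "im_lambda"])
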