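"""Rate laws, Jacobians, nullclines and serialization of the model families."""

import json

import numpy as np
import pytest
import sympy as sp

from oscirc.models import (Design, ModelParams, ModelSpec, evaluate_jacobian,
                           evaluate_rhs, make_model, nullclines, to_hours)

from conftest import REF, random_states


def sympy_field(design, alpha, beta, gamma, sigma, sigma_prime, delta, n, m):
    """Independent symbolic construction of each design's vector field."""
    x, y = sp.symbols("x y", nonnegative=True)
    act = (1 + alpha * x**n) / (1 + x**n)   # shared activator occupancy factor
    if design in ("DESIGN_I", "ATKINSON_COMP"):
        prod = beta * (1 + alpha * x**n) / (1 + x**n + sigma * y**m)
        loss = x
        rep = gamma * act
    elif design == "DESIGN_II":
        prod = beta * act
        loss = x * (1 + sigma_prime * y)
        rep = gamma * act
    elif design in ("DESIGN_III", "GENERALIZED_III"):
        prod = beta * act / (1 + sigma * y**m)
        loss = x
        rep = gamma * act
    else:  # SMOLEN: both genes share the competitively regulated promoter
        prod = beta * (1 + alpha * x**n) / (1 + x**n + sigma * y**m)
        loss = x
        rep = gamma * (1 + alpha * x**n) / (1 + x**n + sigma * y**m)
    fx = delta * (prod - loss)
    fy = delta * rep - y
    J = sp.Matrix([fx, fy]).jacobian([x, y])
    return (sp.lambdify((x, y), (fx, fy), "numpy"),
            sp.lambdify((x, y), J, "numpy"))


DESIGN_KW = {
    "DESIGN_I": dict(n=2, m=2),
    "DESIGN_II": dict(n=2, m=2, sigma_prime=0.7),
    "DESIGN_III": dict(n=2, m=2),
    "GENERALIZED_III": dict(n=3, m=2),
    "ATKINSON_COMP": dict(n=4, m=4),
    "SMOLEN": dict(n=2, m=1),
}


@pytest.mark.parametrize("design", list(DESIGN_KW))
def test_rhs_and_jacobian_match_symbolic_oracle(design, rng):
    """Every family's rate law and analytic Jacobian agree with an
    independently built sympy model at random admissible states."""
    kw = DESIGN_KW[design]
    params = dict(alpha=50.0, beta=0.7, gamma=0.06, sigma=1.3,
                  sigma_prime=kw.get("sigma_prime", 0.0), delta=10.0,
                  n=kw["n"], m=kw["m"])
    f_ref, J_ref = sympy_field(design, **params)
    model = make_model(design, alpha=50.0, beta=0.7, gamma=0.06, sigma=1.3,
                       sigma_prime=kw.get("sigma_prime", 0.0),
                       delta_ratio=10.0, n=kw["n"], m=kw["m"])
    for x, y in random_states(rng, 50):
        got = model.rhs(x, y)
        want = f_ref(x, y)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12)
        assert np.allclose(model.jac(x, y), np.asarray(J_ref(x, y), float),
                           rtol=1e-9, atol=1e-9)


def test_jacobian_matches_finite_differences(design_grid, rng):
    h = 1e-6
    for model in design_grid:
        for x, y in random_states(rng, 40, lo=1e-2, hi=20.0):
            J = model.jac(x, y)
            Jfd = np.empty((2, 2))
            for j, (dx, dy) in enumerate([(h, 0), (0, h)]):
                fp = np.array(model.rhs(x + dx, y + dy))
                fm = np.array(model.rhs(x - dx, y - dy))
                Jfd[:, j] = (fp - fm) / (2 * h)
            scale = np.abs(J).max() + 1.0
            assert np.abs(J - Jfd).max() / scale < 1e-5


def test_sigma_zero_collapses_competition_onto_non_competition(rng):
    """With sigma=0 the summed and multiplied denominators coincide, so
    Designs I and III define the same vector field."""
    m1 = make_model("DESIGN_I", **REF | dict(sigma=0.0, beta=0.8, gamma=0.04))
    m3 = make_model("DESIGN_III", **REF | dict(sigma=0.0, beta=0.8, gamma=0.04))
    for x, y in random_states(rng, 100):
        assert m1.rhs(x, y) == pytest.approx(m3.rhs(x, y), rel=1e-14)


def test_generalized_and_atkinson_reduce_to_base_designs(rng):
    gen = make_model("GENERALIZED_III", alpha=50, beta=0.5, gamma=0.05,
                     sigma=1, delta_ratio=10, n=2, m=2)
    base = make_model("DESIGN_III", alpha=50, beta=0.5, gamma=0.05,
                      sigma=1, delta_ratio=10)
    atk = make_model("ATKINSON_COMP", alpha=50, beta=0.5, gamma=0.05,
                     sigma=1, delta_ratio=10)
    for x, y in random_states(rng, 50):
        assert gen.rhs(x, y) == pytest.approx(base.rhs(x, y), rel=1e-14)
        # the Atkinson effective model is the competition rate law with
        # quartic occupancy (two dimers per DNA loop)
        f_ref, _ = sympy_field("DESIGN_I", alpha=50.0, beta=0.5, gamma=0.05,
                               sigma=1.0, sigma_prime=0.0, delta=10.0, n=4, m=4)
        assert atk.rhs(x, y) == pytest.approx(tuple(np.atleast_1d(v).item()
                                                    for v in f_ref(x, y)), rel=1e-12)


@pytest.mark.parametrize("bad", [
    dict(design="NO_SUCH_DESIGN"),
    dict(design="ATKINSON_COMP", n=3, m=4),
    dict(design="DESIGN_I", sigma_prime=1.0),
    dict(design="DESIGN_III", n=2.5),
    dict(design="SMOLEN", m=0),
])
def test_make_model_rejects_invalid_requests(bad):
    design = bad.pop("design")
    with pytest.raises(ValueError):
        make_model(design, alpha=50, beta=1, gamma=0.05, delta_ratio=10, **bad)


def test_rhs_rejects_negative_states():
    m = make_model("DESIGN_III", **REF)
    with pytest.raises(ValueError):
        m.rhs(-0.1, 0.5)


def test_nullclines_intersections_are_fixed_points():
    from oscirc.equilibria import find_fixed_points
    m = make_model("DESIGN_III", **REF | dict(beta=0.3, gamma=0.01))
    xs = np.geomspace(1e-4, 50, 4000)
    y_x, y_y = nullclines(m, xs)
    diff = y_x - y_y
    ok = np.isfinite(diff)
    crossings = np.nonzero(np.sign(diff[ok])[:-1] * np.sign(diff[ok])[1:] < 0)[0]
    fps = find_fixed_points(m)
    assert len(crossings) == len(fps)
    xs_ok = xs[ok]
    for i, r in zip(sorted(crossings), fps):
        assert xs_ok[i] <= r.x_star <= xs_ok[i + 2]


def test_repressor_nullcline_limits():
    """y_y runs from Delta*gamma at x=0 to alpha*Delta*gamma at saturation."""
    m = make_model("DESIGN_I", **REF | dict(gamma=0.05))
    p = m.params
    y0 = m.y_nullcline(np.array([1e-9]))[0]
    yinf = m.y_nullcline(np.array([1e6]))[0]
    assert y0 == pytest.approx(p.delta_ratio * p.gamma, rel=1e-6)
    assert yinf == pytest.approx(p.alpha * p.delta_ratio * p.gamma, rel=1e-4)


def test_activator_nullcline_closed_form_design_iii():
    """For the non-competitive design, dx/dtau = 0 inverts to
    y = sqrt((beta*g(x)/x - 1)/sigma)."""
    m = make_model("DESIGN_III", **REF | dict(beta=1.0))
    x = np.array([1.0])
    g = (1 + 50 * x**2) / (1 + x**2)
    expected = np.sqrt(1.0 * g / x - 1.0)
    assert m.x_nullcline(x)[0] == pytest.approx(expected[0], rel=1e-12)


def test_design_ii_nullcline_is_square_of_design_iii():
    """With sigma' matched to sigma, the post-translational design's
    activator nullcline is the square of the non-competitive one."""
    m2 = make_model("DESIGN_II", **REF | dict(beta=0.6, sigma_prime=1.0))
    m3 = make_model("DESIGN_III", **REF | dict(beta=0.6))
    xs = np.geomspace(0.01, 5, 200)
    y2 = m2.x_nullcline(xs)
    y3 = m3.x_nullcline(xs)
    ok = np.isfinite(y2) & np.isfinite(y3)
    assert ok.sum() > 50
    assert np.allclose(y2[ok], y3[ok] ** 2, rtol=1e-10)


def test_nullclines_require_positive_sorted_grid():
    m = make_model("DESIGN_I", **REF)
    with pytest.raises(ValueError):
        nullclines(m, np.array([]))
    with pytest.raises(ValueError):
        nullclines(m, np.array([0.5, 0.1]))


@pytest.mark.parametrize("period,rate,hours", [
    (2.0, 0.02, 100.0),      # slow repressor turnover: ~4-day oscillations
    (5.0, 1.0, 5.0),
    (6.283, 0.1, 62.83),
])
def test_to_hours_scales_by_repressor_degradation(period, rate, hours):
    assert to_hours(period, rate) == pytest.approx(hours)
    with pytest.raises(ValueError):
        to_hours(period, 0.0)


def test_modelspec_json_round_trip():
    m = make_model("GENERALIZED_III", alpha=50, beta=0.4, gamma=0.02,
                   sigma=2.0, delta_ratio=1.0, n=3, m=2)
    m2 = ModelSpec.from_json(m.to_json())
    assert m2 == m
    assert json.loads(m.to_json())["design"] == "GENERALIZED_III"


def test_trajectories_stay_nonnegative(design_grid):
    from oscirc.dynamics import integrate
    for model in design_grid:
        tr = integrate(model, initial=(0.0, 2.0), t_end=50.0)
        assert tr.x.min() >= 0.0
        assert tr.y.min() >= 0.0
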