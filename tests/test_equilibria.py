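"""Fixed-point location, eigenvalue classification, damped-onset detection."""

import dataclasses

import numpy as np
import pytest

from oscirc.equilibria import (STABLE_FOCUS, STABLE_NODE, ConflictingStabilityError,
                               NotAnEquilibriumError, cell_stability,
                               classify_fixed_point, damped_onset,
                               find_fixed_points, stability_map)
from oscirc.models import ModelParams, make_model

from conftest import REF


def brute_force_roots(model, x_lo=1e-6, x_hi=100.0, n=200_000):
    """Independent 1-D oracle: dense sign-change scan of dx/dtau along the
    repressor nullcline, bisected by hand."""
    xs = np.geomspace(x_lo, x_hi, n)
    ys = model.y_nullcline(xs)
    F = np.array([model.rhs(float(x), float(y))[0] for x, y in zip(xs, ys)])
    roots = []
    for i in np.nonzero(np.sign(F[:-1]) * np.sign(F[1:]) < 0)[0]:
        a, b = xs[i], xs[i + 1]
        for _ in range(80):
            mid = np.sqrt(a * b)
            fm = model.rhs(mid, float(model.y_nullcline(np.array([mid]))[0]))[0]
            if np.sign(fm) == np.sign(F[i]):
                a = mid
            else:
                b = mid
        roots.append(np.sqrt(a * b))
    return roots


def test_beta_zero_has_unique_basal_equilibrium():
    """Without activator production the system settles at (0, Delta*gamma)
    with eigenvalues {-Delta, -1}."""
    m = make_model("DESIGN_III", **REF | dict(beta=0.0, gamma=0.05))
    recs = find_fixed_points(m)
    assert len(recs) == 1
    r = recs[0]
    assert r.x_star == pytest.approx(0.0, abs=1e-12)
    assert r.y_star == pytest.approx(10.0 * 0.05, rel=1e-9)
    assert r.stability == STABLE_NODE
    eig = sorted(c.real for c in r.eigenvalues)
    assert eig == pytest.approx([-10.0, -1.0], rel=1e-9)


def test_fixed_points_match_brute_force_oracle():
    m = make_model("DESIGN_III", **REF | dict(beta=0.2, gamma=0.05))
    expected = brute_force_roots(m)
    got = find_fixed_points(m)
    assert len(got) == len(expected)
    for r, x_ref in zip(got, sorted(expected)):
        assert r.x_star == pytest.approx(x_ref, rel=1e-6)
        assert r.residual < 1e-9


def test_three_crossing_multistable_case_is_found():
    """The competition design develops three nullcline crossings along a
    beta scan (the route to its SNIC exits)."""
    m = make_model("DESIGN_I", **REF | dict(beta=0.2, gamma=0.01))
    recs = find_fixed_points(m)
    assert len(recs) == 3
    assert len(brute_force_roots(m)) == 3
    assert sorted(r.stability for r in recs).count("saddle") == 1


def test_fixed_point_count_is_odd(rng):
    for _ in range(15):
        beta = float(np.exp(rng.uniform(np.log(0.02), np.log(5.0))))
        gamma = float(np.exp(rng.uniform(np.log(0.002), np.log(0.5))))
        m = make_model("DESIGN_I", **REF | dict(beta=beta, gamma=gamma))
        n = len(find_fixed_points(m))
        assert n % 2 == 1, (beta, gamma, n)


def test_classification_consistent_with_trace_determinant():
    for beta, gamma in [(0.1, 0.01), (0.3, 0.05), (1.58, 0.079), (5.0, 0.3)]:
        m = make_model("DESIGN_III", **REF | dict(beta=beta, gamma=gamma))
        for r in find_fixed_points(m):
            J = m.jac(r.x_star, r.y_star)
            tr, det = np.trace(J), np.linalg.det(J)
            disc = tr * tr - 4 * det
            if det < 0:
                assert r.stability == "saddle"
            elif disc < 0:
                assert r.stability == ("stable-focus" if tr < 0 else "unstable-focus")
            else:
                assert r.stability == ("stable-node" if tr < 0 else "unstable-node")


def test_classify_fixed_point_refines_and_rejects():
    m = make_model("DESIGN_III", **REF | dict(beta=0.0, gamma=0.05))
    r = classify_fixed_point(m, (1e-8, 0.5 + 1e-7))
    assert r.residual < 1e-9
    assert r.stability == STABLE_NODE
    with pytest.raises(NotAnEquilibriumError):
        classify_fixed_point(m, (5.0, 5.0))


def test_classification_agrees_with_long_run_integration(rng):
    """A stable equilibrium predicted from eigenvalues is where the flow
    actually ends up; no stable equilibrium means it does not settle."""
    from oscirc.dynamics import SUSTAINED, classify_asymptotics
    checked = 0
    while checked < 12:
        beta = float(np.exp(rng.uniform(np.log(0.05), np.log(3.0))))
        gamma = float(np.exp(rng.uniform(np.log(0.005), np.log(0.3))))
        m = make_model("DESIGN_III", **REF | dict(beta=beta, gamma=gamma))
        stable = [r for r in find_fixed_points(m) if r.is_stable]
        s = classify_asymptotics(m)
        if s.verdict == SUSTAINED:
            assert not stable, (beta, gamma)
        else:
            assert stable, (beta, gamma)
        checked += 1


def test_damped_onset_matches_dense_discriminant_scan():
    """Bisected complexification onset equals a dense scan of the
    eigenvalue discriminant's sign change."""
    fixed = ModelParams(**REF | dict(gamma=0.05))
    onset = damped_onset("DESIGN_III", "beta", 0.02, 0.15, fixed)
    assert onset is not None
    grid = np.geomspace(0.02, 0.15, 2_000)
    dense = None
    prev = None
    for b in grid:
        m = make_model("DESIGN_III", dataclasses.replace(fixed, beta=float(b)))
        stab = [r for r in find_fixed_points(m) if r.is_stable]
        state = stab[0].stability if stab else "none"
        if prev is not None and prev == STABLE_NODE and state == STABLE_FOCUS:
            dense = b
            break
        prev = state
    assert dense is not None
    assert onset == pytest.approx(dense, rel=2e-3)


def test_damped_onset_none_when_eigenvalues_stay_real():
    fixed = ModelParams(**REF | dict(gamma=0.05))
    assert damped_onset("DESIGN_III", "beta", 0.02, 0.05, fixed, n_scan=40) is None
    with pytest.raises(ValueError):
        damped_onset("DESIGN_III", "nope", 0.02, 0.05, fixed)


def test_stability_map_single_cell_degenerates_to_classification():
    fixed = ModelParams(**REF)
    rec = stability_map("DESIGN_III", ("beta", "gamma"),
                        [0.3], [0.05], fixed)
    assert len(rec) == 1
    m = make_model("DESIGN_III", dataclasses.replace(fixed, beta=0.3, gamma=0.05))
    label, re_max, im = cell_stability(m)
    assert rec[0]["klass"] == label


def test_non_competitive_design_has_larger_oscillation_prone_area():
    """Across the (beta, gamma) plane the non-competitive design shows
    damped or sustained eigenvalue signatures over more cells."""
    fixed = ModelParams(**REF)
    b = np.geomspace(0.05, 5, 10)
    g = np.geomspace(0.005, 0.5, 10)
    areas = {}
    for d in ("DESIGN_I", "DESIGN_III"):
        rec = stability_map(d, ("beta", "gamma"), b, g, fixed)
        areas[d] = sum(1 for r in rec if r["klass"] != "no-oscillation")
    assert areas["DESIGN_III"] >= areas["DESIGN_I"]
    assert areas["DESIGN_III"] > 0


def test_stability_map_agrees_with_integration_verdicts():
    from oscirc.dynamics import SUSTAINED, classify_asymptotics
    fixed = ModelParams(**REF)
    b = np.geomspace(0.05, 3, 4)
    g = np.geomspace(0.01, 0.2, 3)
    rec = stability_map("DESIGN_III", ("beta", "gamma"), b, g, fixed)
    for r in rec:
        m = make_model("DESIGN_III",
                       dataclasses.replace(fixed, beta=float(r["p1"]), gamma=float(r["p2"])))
        s = classify_asymptotics(m)
        if r["klass"] == "sustained-candidate":
            assert s.verdict == SUSTAINED
        elif r["klass"] == "no-oscillation":
            assert s.verdict == "steady"
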