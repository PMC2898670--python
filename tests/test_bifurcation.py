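"""Transition classification against closed-form normal-form oracles, and
the design-specific bifurcation fingerprints."""

import numpy as np
import pytest

from oscirc.bifurcation import (HOPF_SUB, HOPF_SUPER, SNIC, damped_band,
                                fit_period_divergence, scan_control)
from oscirc.models import ModelParams

from conftest import REF

BOX = ((-1.5, 1.5), (-1.5, 1.5))


class SupercriticalHopf:
    """r' = mu*r - r^3, theta' = 1 — cycle born at mu=0 with r = sqrt(mu)."""

    def __init__(self, mu):
        self.mu = mu

    def rhs(self, x, y):
        r2 = x * x + y * y
        return (self.mu * x - y - x * r2, x + self.mu * y - y * r2)

    def jac(self, x, y):
        return np.array([[self.mu - 3 * x * x - y * y, -1 - 2 * x * y],
                         [1 - 2 * x * y, self.mu - x * x - 3 * y * y]])


class SnicCircle:
    """r' = r(1 - r^2), theta' = mu - sin(theta) (regularized off the circle):
    node and saddle annihilate on the unit circle at mu=1, leaving a cycle
    with period 2*pi/sqrt(mu^2 - 1)."""

    def __init__(self, mu):
        self.mu = mu

    def rhs(self, x, y):
        r2 = x * x + y * y
        return (x * (1 - r2) - y * (self.mu - y),
                y * (1 - r2) + x * (self.mu - y))

    def jac(self, x, y):
        m = self.mu
        return np.array([[1 - 3 * x * x - y * y, -2 * x * y - m + 2 * y],
                         [-2 * x * y + m - y, 1 - x * x - 3 * y * y - x]])


@pytest.fixture(scope="module")
def hopf_diagram():
    return scan_control(lambda mu: SupercriticalHopf(mu), "mu",
                        np.linspace(-0.2, 0.3, 51), search_box=BOX)


@pytest.fixture(scope="module")
def snic_diagram():
    return scan_control(lambda mu: SnicCircle(mu), "mu",
                        np.linspace(0.5, 1.5, 51), search_box=BOX, t_cap=800.0)


def test_normal_form_hopf_detected_supercritical(hopf_diagram):
    events = [e for e in hopf_diagram.events if e.kind != "saddle_node"]
    assert len(events) == 1
    e = events[0]
    assert e.kind == HOPF_SUPER
    assert e.control_value == pytest.approx(0.0, abs=0.01)
    assert e.evidence["amplitude_exponent"] == pytest.approx(0.5, abs=0.15)
    assert not e.evidence["fp_collision"]


def test_normal_form_snic_detected_with_period_law(snic_diagram):
    events = [e for e in snic_diagram.events if e.kind != "saddle_node"]
    assert len(events) == 1
    e = events[0]
    assert e.kind == SNIC
    assert e.control_value == pytest.approx(1.0, abs=0.005)
    assert e.evidence["period_exponent"] == pytest.approx(-0.5, abs=0.1)
    assert e.evidence["fp_collision"]


def test_snic_period_matches_closed_form(snic_diagram):
    vals = snic_diagram.control_values
    for mu in (1.1, 1.3):
        i = int(np.argmin(np.abs(vals - mu)))
        want = 2 * np.pi / np.sqrt(vals[i] ** 2 - 1)
        assert snic_diagram.periods[i] == pytest.approx(want, rel=0.01)


def test_fit_period_divergence_on_exact_law():
    mu = np.array([1.001, 1.003, 1.01, 1.03, 1.1])
    T = 2 * np.pi / np.sqrt(mu**2 - 1)
    p, _ = fit_period_divergence(mu, T, 1.0, +1)
    assert p == pytest.approx(-0.5, abs=0.05)


@pytest.fixture(scope="module")
def design_scans():
    fixed = ModelParams(**REF | dict(gamma=0.05))
    grid = np.geomspace(0.02, 8, 70)
    return {d: scan_control(d, "beta", grid, fixed)
            for d in ("DESIGN_I", "DESIGN_III")}


def test_non_competitive_band_is_hopf_bounded_with_damped_flanks(design_scans):
    d = design_scans["DESIGN_III"]
    kinds = [e.kind for e in d.events if e.kind != "saddle_node"]
    assert len(kinds) == 2
    assert all(k in (HOPF_SUPER, HOPF_SUB) for k in kinds)
    bands = damped_band(d)
    for e in d.events:
        if e.kind in (HOPF_SUPER, HOPF_SUB):
            assert any(abs(lo - e.control_value) / e.control_value < 0.02
                       or abs(hi - e.control_value) / e.control_value < 0.02
                       for lo, hi in bands), (e.control_value, bands)


def test_competition_band_exits_through_snic_without_damped_flank(design_scans):
    d = design_scans["DESIGN_I"]
    sus = [i for i, v in enumerate(d.verdicts) if v == "sustained"]
    exit_value = d.control_values[sus[-1]]
    exit_events = [e for e in d.events
                   if e.kind not in ("saddle_node",) and e.control_value >= exit_value * 0.9]
    assert len(exit_events) == 1
    e = exit_events[0]
    assert e.kind == SNIC
    assert not e.evidence["damped_adjacent"]
    assert e.evidence["period_exponent"] == pytest.approx(-0.5, abs=0.1)


def test_hopf_onset_frequency_equals_imaginary_part(design_scans):
    """At each Hopf event the cycle frequency at onset equals |Im lambda|
    at the crossing within 5%."""
    from oscirc.dynamics import SUSTAINED, classify_asymptotics
    from oscirc.equilibria import find_fixed_points
    from oscirc.models import make_model
    d = design_scans["DESIGN_III"]
    hopfs = [e for e in d.events if e.kind in (HOPF_SUPER, HOPF_SUB)]
    assert hopfs
    e = hopfs[0]
    mu = e.control_value
    m_at = make_model("DESIGN_III", **REF | dict(beta=mu * 0.999, gamma=0.05))
    recs = [r for r in find_fixed_points(m_at) if r.is_focus]
    im = abs(recs[0].eigenvalues[0].imag)
    s = classify_asymptotics(
        make_model("DESIGN_III", **REF | dict(beta=mu * 1.01, gamma=0.05)))
    assert s.verdict == SUSTAINED
    assert 2 * np.pi / s.period == pytest.approx(im, rel=0.05)


def test_snic_coincides_with_equilibrium_count_change(design_scans):
    d = design_scans["DESIGN_I"]
    snics = [e for e in d.events if e.kind == SNIC]
    assert snics
    for e in snics:
        n_osc, n_no = e.evidence["fp_count_change"]
        assert abs(n_no - n_osc) == 2


def test_damped_band_endpoint_matches_damped_onset(design_scans):
    """Cross-module consistency: the refined damped-band edge agrees with
    the bisected complexification onset."""
    from oscirc.equilibria import damped_onset
    d = design_scans["DESIGN_III"]
    bands = damped_band(d)
    assert bands
    lo = bands[0][0]
    onset = damped_onset("DESIGN_III", "beta", lo * 0.5, lo * 1.5,
                         ModelParams(**REF | dict(gamma=0.05)))
    assert onset == pytest.approx(lo, rel=2e-3)


def test_undecided_cells_propagate_as_gaps():
    """A scan crossing the degenerate infinite-period point keeps the
    undecided cell visible rather than interpolating it."""
    d = scan_control(lambda mu: SnicCircle(mu), "mu",
                     np.linspace(0.96, 1.04, 5), search_box=BOX, t_cap=300.0,
                     classify_events=False)
    assert set(d.verdicts) <= {"steady", "damped", "sustained", "undecided"}
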