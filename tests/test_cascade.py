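"""Effector-caspase cascade ODEs: fixed points, oracles, invariants."""

import numpy as np
import pytest
from scipy.linalg import expm

import ripoptosim as rs
from ripoptosim.cascade import (DeterministicState, cascade_rhs,
                                fret_cleavage_rate, integrate_cascade,
                                _FIELDS, IDX)
from ripoptosim.params import KineticParameters, ValidationError


def quiescent(cfg):
    return DeterministicState.from_initial(cfg.initial_nm)


def test_quiescent_state_is_fixed_point(cfg):
    d = cascade_rhs(quiescent(cfg), cfg.rates, casp8_source=0.0)
    assert all(abs(getattr(d, f)) == 0.0 for f in _FIELDS)


def test_negative_state_rejected(cfg):
    bad = quiescent(cfg)
    bad.casp3_active = -1.0
    with pytest.raises(ValidationError):
        cascade_rhs(bad, cfg.rates, 0.0)


def test_casp3_increases_without_xiap(cfg):
    """With XIAP absent and a constant Casp8 source, active Casp3 rises
    strictly while ProCasp3 remains."""
    c = cfg.replace(initial_nm={"xiap": 0.0})
    traj = integrate_cascade(quiescent(c), c.rates, lambda t: 0.05,
                             (0.0, 120.0), grid=np.linspace(0, 120, 61))
    c3 = traj.series("casp3_active")
    pc3 = traj.series("procasp3")
    inc = np.diff(c3)
    assert np.all(inc[pc3[:-1] > 1.0] > 0)
    assert c3[-1] > c3[0]


def test_linear_subsystem_matches_matrix_exponential(cfg):
    """With autocatalysis, dimerization, XIAP binding and dimer dissociation
    off and Casp8 dimer held fixed, the cascade is linear; the trajectory
    must equal the closed-form matrix-exponential solution."""
    c8d = 0.7  # held fixed: no dissociation, no source
    s0 = DeterministicState(
        casp8_dimer_active=c8d, procasp8=90.0, procasp3=120.0,
        procasp6=60.0, fret_intact=600.0,
    )
    # every bilinear coupling not involving the frozen c8d is switched off
    r = KineticParameters(
        k_casp3_auto=0.0, k_casp8m_dimerization=0.0, kon_xiap_casp3=0.0,
        koff_xiap_casp3=0.0, k_casp8d_diss=0.0, k_casp6_casp8=0.0,
        k_casp3_casp6=0.0,
    )
    A = np.zeros((4, 4))
    # variables: [pc3, c3, fret_i, fret_c]
    A[0, 0] = -r.k_casp8_casp3 * c8d
    A[1, 0] = r.k_casp8_casp3 * c8d
    A[1, 1] = -r.k_basal_deg
    A[2, 2] = -r.k_fret_cleavage * c8d
    A[3, 2] = r.k_fret_cleavage * c8d

    t_end = 200.0
    traj = integrate_cascade(s0, r, lambda t: 0.0, (0.0, t_end),
                             tol=1e-10, grid=np.array([0.0, t_end]))
    y0 = np.array([120.0, 0.0, 600.0, 0.0])
    exact = expm(A * t_end) @ y0
    got = np.array([traj.series(n)[-1] for n in
                    ("procasp3", "casp3_active", "fret_intact", "fret_cleaved")])
    np.testing.assert_allclose(got, exact, rtol=1e-6, atol=1e-8)


def test_integrate_constant_without_source(cfg):
    traj = integrate_cascade(quiescent(cfg), cfg.rates, lambda t: 0.0,
                             (0.0, 300.0), grid=np.linspace(0, 300, 31))
    np.testing.assert_allclose(traj.states[-1], traj.states[0], rtol=1e-9, atol=1e-9)


def test_tolerance_convergence(cfg):
    """Halving the tolerance changes the endpoint by < 1e-6 relative."""
    out = []
    for tol in (1e-8, 5e-9):
        traj = integrate_cascade(quiescent(cfg), cfg.rates, lambda t: 0.02,
                                 (0.0, 400.0), tol=tol,
                                 grid=np.array([0.0, 400.0]))
        out.append(traj.series("fret_cleaved")[-1])
    assert abs(out[1] - out[0]) / abs(out[1]) < 1e-6


def test_fret_conservation_and_monotonicity(cfg):
    traj = integrate_cascade(quiescent(cfg), cfg.rates, lambda t: 0.03,
                             (0.0, 600.0), grid=np.linspace(0, 600, 121))
    fi, fc = traj.series("fret_intact"), traj.series("fret_cleaved")
    total = cfg.initial_nm.fret_substrate
    np.testing.assert_allclose(fi + fc, total, rtol=1e-6)
    assert np.all(np.diff(fc) >= -1e-9)


@pytest.mark.parametrize(
    "state_kw, expected_zero",
    [({"casp8_dimer_active": 0.0, "fret_intact": 600.0}, True),
     ({"casp8_dimer_active": 1.0, "fret_intact": 0.0}, True)],
)
def test_fret_rate_zero_cases(cfg, state_kw, expected_zero):
    s = DeterministicState(**state_kw)
    assert fret_cleavage_rate(s, cfg.rates) == 0.0


def test_fret_rate_bilinear(cfg):
    s1 = DeterministicState(casp8_dimer_active=1.0, fret_intact=600.0)
    s2 = DeterministicState(casp8_dimer_active=2.0, fret_intact=600.0)
    assert fret_cleavage_rate(s2, cfg.rates) == pytest.approx(
        2 * fret_cleavage_rate(s1, cfg.rates))


def test_xiap_suppresses_casp3_for_ten_hours(cfg):
    """At the 63 nM mean XIAP level a small constant Casp8 source keeps
    active Casp3 pinned near zero for at least 600 minutes."""
    traj = integrate_cascade(quiescent(cfg), cfg.rates, lambda t: 0.0005,
                             (0.0, 600.0), grid=np.linspace(0, 600, 61))
    assert traj.series("casp3_active").max() < 0.5  # nM, vs 200 nM zymogen


def test_raising_kcat_ub_delays_threshold_crossing(cfg):
    """A larger Casp3 ubiquitination/degradation constant strictly delays
    the FRET-rate threshold crossing (deterministic full model)."""
    delays = []
    for kcat in (1.0, 1.75, 3.0):
        c = cfg.replace(rates={"kcat_ub": kcat})
        res = rs.deterministic_full_model(c, 5.0, clustering=True)
        assert res.death_time is not None
        delays.append(res.death_time)
    assert delays[0] < delays[1] < delays[2]
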