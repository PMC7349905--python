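"""Dispersion relation, instability criterion and asymptotic limits."""

import numpy as np
import pytest

from polarflow.kinetics import ReactionParams, homogeneous_state
from polarflow.stability import (
    FlowProfile,
    SystemParams,
    dispersion,
    dispersion_relation,
    eigenvector_phase,
    fast_flow_phase_velocity,
    fast_flow_sigma,
    instability_criterion,
    long_wavelength_phase_velocity,
    long_wavelength_sigma,
    slow_flow_coefficient,
    unstable_band,
)


def quadratic_roots(q, state, sys, vf):
    """Independent closed-form oracle: trace/determinant quadratic formula."""
    a11 = -sys.Dc * q * q - 1j * vf * q - state.fc
    a12 = -state.fm
    a21 = state.fc
    a22 = -sys.Dm * q * q + state.fm
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    disc = np.sqrt(tr * tr - 4.0 * det + 0j)
    return 0.5 * (tr - disc), 0.5 * (tr + disc)


def test_q0_eigenvalues_are_zero_and_sigma1(state0, sys0):
    """Uniform perturbations: one neutral mass mode, one reactive mode fm-fc."""
    major, minor = dispersion(0.0, state0, sys0, vf=0.0)
    vals = sorted([major, minor], key=lambda z: z.real)
    assert vals[0] == pytest.approx(state0.fm - state0.fc, abs=1e-12)
    assert vals[1] == pytest.approx(0.0, abs=1e-12)
    major, minor = dispersion(0.0, state0, sys0, vf=37.0)  # flow is invisible at q=0
    assert {round(v.real, 10) for v in (major, minor)} == {
        0.0,
        round(state0.sigma1, 10),
    }


def test_no_flow_dispersion_is_real(state0, sys0):
    q = np.geomspace(1e-4, 10.0, 60)
    sig, minor = dispersion(q, state0, sys0, vf=0.0)
    assert np.all(sig.imag == pytest.approx(0.0, abs=1e-12))
    assert np.all(minor.imag == pytest.approx(0.0, abs=1e-12))


def test_dispersion_matches_quadratic_oracle(rng):
    """Eigenvalues agree with the closed-form roots on random draws."""
    for _ in range(300):
        p = ReactionParams(*rng.uniform(0.2, 5.0, size=4))
        n_bar = rng.uniform(0.5, 10.0)
        state = homogeneous_state(n_bar, p)
        sys_ = SystemParams(
            Dm=rng.uniform(0.0, 1.0), Dc=rng.uniform(0.1, 50.0), reaction=p, n_bar=n_bar
        )
        q = rng.uniform(0.0, 10.0)
        vf = rng.uniform(-100.0, 100.0)
        major, minor = dispersion(q, state, sys_, vf)
        lo, hi = quadratic_roots(q, state, sys_, vf)
        got = sorted([major, minor], key=lambda z: (z.real, z.imag))
        ref = sorted([lo, hi], key=lambda z: (z.real, z.imag))
        scale = max(1.0, abs(ref[0]), abs(ref[1]))
        assert abs(got[0] - ref[0]) < 1e-10 * scale
        assert abs(got[1] - ref[1]) < 1e-10 * scale


def test_nonuniform_flow_rejected(state0):
    sysp = SystemParams(flow=FlowProfile(kind="parabolic", vmax=5.0))
    with pytest.raises(ValueError, match="uniform"):
        dispersion(1.0, state0, sysp, vf=None)
    # explicit vf overrides: the profile is irrelevant to the linearization
    dispersion(1.0, state0, sysp, vf=0.0)


def test_unstable_band_structure(state0, sys0, params):
    q_max, q_star, lam = unstable_band(state0, sys0, vf=0.0)
    assert 0 < q_star < q_max
    assert lam == pytest.approx(2 * np.pi / q_star)
    sig_edge, _ = dispersion(q_max, state0, sys0, 0.0)
    assert abs(sig_edge.real) < 1e-8
    # dense-grid scan oracle: no growing mode beyond q_max, growth inside
    q = np.linspace(1e-3, q_max * 0.999, 200)
    sig, _ = dispersion(q, state0, sys0, 0.0)
    assert np.all(sig.real > 0)
    sig_out, _ = dispersion(np.linspace(q_max * 1.001, 3 * q_max, 50), state0, sys0, 0.0)
    assert np.all(sig_out.real < 0)
    # laterally stable density -> empty band
    st_low = homogeneous_state(0.3, params)
    assert not np.isfinite(unstable_band(st_low, sys0, vf=0.0)[0])


def test_instability_criterion_limits(state0, sys0):
    ok0, thr0 = instability_criterion(state0, sys0, vf=0.0)
    assert thr0 == pytest.approx(-sys0.Dm / sys0.Dc, rel=1e-12)
    assert ok0  # defaults are laterally unstable
    ok_inf, thr_inf = instability_criterion(state0, sys0, vf=1e5)
    assert -1e-6 < thr_inf < 0.0  # fast flow: threshold -> 0 from below
    assert ok_inf == (state0.s_nc < 0)
    # threshold magnitude decreases monotonically with |vf|
    thr = [instability_criterion(state0, sys0, vf)[1] for vf in (0, 1, 5, 20, 100, 1000)]
    assert all(abs(b) < abs(a) for a, b in zip(thr[:-1], thr[1:]))


def test_criterion_handles_zero_cytosolic_diffusion(state0, sys0):
    import dataclasses

    sys_d0 = dataclasses.replace(sys0, Dc=0.0)
    with pytest.raises(ValueError):
        instability_criterion(state0, sys_d0, vf=0.0)
    ok, thr = instability_criterion(state0, sys_d0, vf=50.0)
    assert np.isfinite(thr) and thr < 0  # flow alone can destabilize


def test_criterion_requires_homogeneous_stability(params, sys0):
    unstable = homogeneous_state(5.0, params)
    fake = type(unstable)(
        n_bar=5, m_star=1, c_star=4, fm=2.0, fc=1.0, s_nc=-2.0, sigma1=1.0
    )
    with pytest.raises(ValueError):
        instability_criterion(fake, sys0, vf=0.0)


def test_long_wavelength_expansion_converges(state0, sys0):
    """Relative error of the small-q expansion decays at least linearly."""
    vf = 20.0
    qs = np.array([1e-4, 1e-3, 1e-2, 1e-1])
    errs = []
    for q in qs:
        full, _ = dispersion(q, state0, sys0, vf)
        approx = long_wavelength_sigma(q, state0, sys0, vf)
        errs.append(abs(approx - full) / abs(full))
    errs = np.array(errs)
    assert errs[0] < 1e-5
    # the relative error vanishes at least linearly as q -> 0: err/q is
    # monotone in q (empirically it decays quadratically)
    assert np.all(np.diff(errs / qs) > 0)
    # no flow -> expansion purely real
    assert long_wavelength_sigma(0.05, state0, sys0, 0.0).imag == 0.0


def test_long_wavelength_phase_velocity(state0, sys0):
    vf = 20.0
    q = 1e-4
    sig, _ = dispersion(q, state0, sys0, vf)
    v_exp = long_wavelength_phase_velocity(state0, vf)
    assert -sig.imag / q == pytest.approx(v_exp, rel=1e-3)
    assert v_exp == pytest.approx(vf * state0.s_nc / (1 + state0.s_nc))


def test_slow_flow_coefficient_positive_and_converged(state0, sys0):
    q_max, q_star, _ = unstable_band(state0, sys0, 0.0)
    q = np.linspace(0.05 * q_max, 0.95 * q_max, 20)
    A3 = slow_flow_coefficient(q, state0, sys0, vf_eps=1e-3)
    A4 = slow_flow_coefficient(q, state0, sys0, vf_eps=1e-4)
    assert np.all(A3 > 0)
    np.testing.assert_allclose(A3, A4, rtol=1e-2)  # step-halving consistency


@pytest.mark.parametrize("vf", [0.1, 1.0, 10.0, 100.0, -0.1, -1.0, -10.0, -100.0])
def test_growing_modes_drift_upstream(state0, sys0, vf):
    """sign(Im sigma) = sign(vf) on the unstable band, i.e. the phase
    velocity -Im sigma / q opposes the flow."""
    q_max, _, _ = unstable_band(state0, sys0, vf=0.0)
    q = np.linspace(0.05 * q_max, 0.95 * q_max, 25)
    sig, _ = dispersion(q, state0, sys0, vf)
    assert np.all(np.sign(sig.imag) == np.sign(vf))


def test_fast_flow_limit(state0, sys0):
    import dataclasses

    _, q_star, _ = unstable_band(state0, sys0, 0.0)
    vf = 1e4
    approx = fast_flow_sigma(q_star, state0, sys0, vf)
    full, _ = dispersion(q_star, state0, sys0, vf)
    assert abs(approx - full) / abs(full) < 0.02
    # real part independent of Dc and vf
    assert approx.real == fast_flow_sigma(q_star, state0, dataclasses.replace(sys0, Dc=1e3), vf).real
    assert approx.real == fast_flow_sigma(q_star, state0, sys0, 10 * vf).real
    # phase-velocity magnitude decays as 1/vf
    v1 = fast_flow_phase_velocity(q_star, state0, vf)
    v2 = fast_flow_phase_velocity(q_star, state0, 10 * vf)
    assert abs(v2) == pytest.approx(abs(v1) / 10.0)


def test_dispersion_relation_summary(state0, sys0):
    disp = dispersion_relation(state0, sys0, vf=20.0, n_q=128)
    assert disp.unstable
    assert disp.q_grid[0] == 0.0
    assert np.isnan(disp.v_phase[0])
    inside = (disp.q_grid > 0.05) & (disp.q_grid < disp.q_max * 0.95)
    assert np.all(disp.v_phase[inside] < 0)  # upstream for vf > 0


def test_eigenvector_phase_saturates(state0, sys0):
    """The cytosol-membrane eigenvector phase shift grows with flow and
    approaches a finite large-flow limit (diagnostic, not an assumption)."""
    _, q_star, _ = unstable_band(state0, sys0, 0.0)
    ph0 = eigenvector_phase(q_star, state0, sys0, vf=0.0)
    phases = [abs(eigenvector_phase(q_star, state0, sys0, vf)) for vf in (1, 10, 100)]
    assert abs(ph0) in (pytest.approx(0.0, abs=1e-12), pytest.approx(np.pi, abs=1e-12))
    hi1 = eigenvector_phase(q_star, state0, sys0, 1e5)
    hi2 = eigenvector_phase(q_star, state0, sys0, 1e6)
    assert hi1 == pytest.approx(hi2, abs=1e-3)  # saturation
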