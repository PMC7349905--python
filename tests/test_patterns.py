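"""Peak tracking, phase-plane loops, classification, regional instability."""

import dataclasses

import numpy as np
import pytest

from polarflow.dynamics import ConcentrationField, SimulationResult, make_initial, simulate
from polarflow.kinetics import homogeneous_state, nullcline_c
from polarflow.patterns import (
    classify_pattern,
    inflection_state,
    phase_trajectory,
    predict_vp_lsa,
    regional_instability,
    track_peak,
    unstable_density_range,
)
from polarflow.stability import SystemParams


def synthetic_kymograph(sys_, v, N=128, T=41, width=0.8, t_step=2.0):
    """Gaussian bump translating at speed v with periodic wrap (synthetic
    stand-in for a simulation, used to validate the tracker)."""
    dx = sys_.L / N
    x = (np.arange(N) + 0.5) * dx
    times = np.arange(T) * t_step
    m = np.empty((T, N))
    for i, t in enumerate(times):
        d = x - (sys_.L / 2 + v * t)
        d -= sys_.L * np.round(d / sys_.L)
        m[i] = 1.0 + 10.0 * np.exp(-0.5 * (d / width) ** 2)
    c = np.full_like(m, 0.3)
    return SimulationResult(times=times, x=x, m=m, c=c, params=sys_)


@pytest.mark.parametrize("v", [0.0, 0.013, -0.021, 0.06])
def test_track_peak_recovers_known_speed(sys0, v):
    res = synthetic_kymograph(sys0, v)
    track = track_peak(res)
    assert track.steady and track.n_peaks == 1
    assert track.v_p == pytest.approx(v, abs=2e-4)


def test_track_peak_withholds_speed_for_multiple_peaks(sys0):
    res = synthetic_kymograph(sys0, 0.01)
    res.m += np.roll(res.m, res.m.shape[1] // 2, axis=1)  # second identical peak
    track = track_peak(res)
    assert track.n_peaks > 1
    assert np.isnan(track.v_p)


def test_track_peak_unwraps_across_boundary(sys0):
    # fast enough to wrap around the domain within the window
    res = synthetic_kymograph(sys0, 0.2, T=81)
    track = track_peak(res)
    assert track.v_p == pytest.approx(0.2, abs=1e-3)
    assert track.positions.max() > sys0.L  # unwrapped coordinates keep going


def test_stationary_pattern_lies_on_flux_balance_subspace(relaxed_peak, sys0):
    """No flow: phase-plane points collinear on the slope -Dm/Dc line, the
    loop closes, and the two nullcline crossings coincide."""
    traj = phase_trajectory(relaxed_peak, sys0.reaction, sys0, vf=0.0)
    data_range = relaxed_peak.m.max() - relaxed_peak.m.min()
    assert traj.fbs_slope == -sys0.Dm / sys0.Dc
    assert traj.fbs_max_distance < 1e-3 * data_range
    assert abs(traj.loop_area) < 1e-6 * relaxed_peak.m.max() * relaxed_peak.c.max()
    assert traj.cL == pytest.approx(traj.cR, abs=1e-6)
    # crossings satisfy the nullcline relation
    assert traj.cL == pytest.approx(float(nullcline_c(traj.mL, sys0.reaction)), abs=1e-3)


def test_flow_opens_loop_with_upstream_excess(relaxed_peak, sys0):
    s = sys0.with_flow(vf=20.0, t0=0.0)
    res = simulate(relaxed_peak, s, t_end=300.0, save_every=50.0)
    traj = phase_trajectory(res.field(-1), sys0.reaction, s)
    assert traj.cL > traj.cR  # cytosol piles up on the upstream flank
    assert abs(traj.loop_area) > 0.01
    # reversed flow swaps the roles of the two flanks
    s_neg = sys0.with_flow(vf=-20.0, t0=0.0)
    res_neg = simulate(relaxed_peak, s_neg, t_end=300.0, save_every=50.0)
    traj_neg = phase_trajectory(res_neg.field(-1), sys0.reaction, s_neg)
    assert traj_neg.cL > traj_neg.cR


def test_phase_trajectory_needs_a_pattern(sys0):
    flat = make_initial("homogeneous-noise", sys0, N=64, amplitude=0.0)
    with pytest.raises(RuntimeError, match="too weak|crossing"):
        phase_trajectory(flat, sys0.reaction, sys0)


def test_classify_homogeneous(sys0):
    flat = make_initial("homogeneous-noise", sys0, N=64, amplitude=1e-6, seed=0)
    cls = classify_pattern(flat, sys0.reaction, sys0)
    assert cls.label == "homogeneous"


def test_classify_synthetic_mesa_and_peak(sys0):
    """Trapezoid with a long flat top reads as mesa; a narrow bump as peak."""
    N = 256
    dx = sys0.L / N
    x = (np.arange(N) + 0.5) * dx
    half = sys0.L / 2
    plateau, ramp = 3.0, 0.5
    d = np.abs(x - half)
    mesa_m = 1.0 + 9.0 * np.clip((plateau / 2 + ramp - d) / ramp, 0.0, 1.0)
    mesa = ConcentrationField(x=x, m=mesa_m, c=np.full(N, 0.2))
    assert classify_pattern(mesa, sys0.reaction, sys0).label == "mesa"
    peak_m = 1.0 + 9.0 * np.exp(-0.5 * ((x - half) / 0.4) ** 2)
    peak = ConcentrationField(x=x, m=peak_m, c=np.full(N, 0.2))
    assert classify_pattern(peak, sys0.reaction, sys0).label == "peak"


def test_relaxed_default_pattern_is_peak(relaxed_peak, sys0):
    assert classify_pattern(relaxed_peak, sys0.reaction, sys0).label == "peak"


def test_unstable_density_range(sys0, params):
    n_lo, n_hi = unstable_density_range(params, sys0, vf=0.0)
    assert n_lo < 5.0 < n_hi  # canonical density sits inside
    # equal diffusion: requires s_nc < -1, excluded by homogeneous stability
    sys_eq = dataclasses.replace(sys0, Dm=10.0, Dc=10.0)
    lo, hi = unstable_density_range(params, sys_eq, vf=0.0)
    assert np.isnan(lo) and np.isnan(hi)
    # flow widens the unstable interval
    n_lo_f, n_hi_f = unstable_density_range(params, sys0, vf=20.0)
    assert n_lo_f < n_lo
    assert n_hi_f >= n_hi


def test_regional_instability_masks(sys0, params):
    n_lo, _ = unstable_density_range(params, sys0, vf=0.0)
    N = 128
    dx = sys0.L / N
    x = (np.arange(N) + 0.5) * dx
    # laterally stable homogeneous state: nothing marked
    st = homogeneous_state(0.8 * n_lo, params)
    flat = ConcentrationField(x=x, m=np.full(N, st.m_star), c=np.full(N, st.c_star))
    sys_low = dataclasses.replace(sys0, n_bar=0.8 * n_lo)
    mask, trig = regional_instability(flat, params, sys_low)
    assert not mask.any() and not trig
    # a wide region pushed into the unstable range triggers
    n_prof = np.full(N, 0.8 * n_lo)
    n_prof[N // 2 :] = 5.0
    st5 = homogeneous_state(5.0, params)
    m_prof = np.where(n_prof == 5.0, st5.m_star, st.m_star)
    bumped = ConcentrationField(x=x, m=m_prof, c=n_prof - m_prof)
    mask2, trig2 = regional_instability(bumped, params, sys_low)
    assert mask2[N // 2 :].all() and not mask2[: N // 2].any()
    assert trig2


def test_predict_vp_lsa_signs(relaxed_peak, sys0):
    st_i = inflection_state(relaxed_peak, sys0.reaction, sys0)
    # the inflection composition is itself laterally unstable
    assert st_i.s_nc < -sys0.Dm / sys0.Dc
    assert predict_vp_lsa(st_i, sys0, 0.0) == pytest.approx(0.0, abs=1e-12)
    v20 = predict_vp_lsa(st_i, sys0, 20.0)
    assert v20 < 0  # upstream
    v_neg = predict_vp_lsa(st_i, sys0, -20.0)
    assert v_neg == pytest.approx(-v20, rel=1e-8)
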