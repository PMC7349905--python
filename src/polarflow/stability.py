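"""Linear stability of the uniform state under uniform cytosolic flow.

Linearizing the transport--reaction dynamics around a uniform equilibrium
``(m*, c*)`` and expanding perturbations in Fourier modes ``exp(sigma*t + i*q*x)``
gives, for each wavenumber ``q``, the 2x2 eigenvalue problem with Jacobian
(state ordering (c, m))::

    J(q) = [[-Dc q^2 - i vf q - fc,  -fm],
            [ fc,                    -Dm q^2 + fm]]

The eigenvalue with the larger real part, sigma(q), decides lateral
stability.  Key facts implemented and exposed here:

* at q = 0 the two eigenvalues are exactly {0, fm - fc}; the zero mode
  reflects mass conservation (perturbations along the nullcline);
* without flow sigma(q) is purely real for homogeneously stable states; with
  flow Im sigma != 0 and every growing mode drifts with phase velocity
  -Im sigma / q, always directed against the flow;
* the long-wavelength expansion of sigma(q) yields the instability
  criterion s_nc < -(Dm/Dc) / (1 + vf^2 / ((1+s_nc)^2 Dc fc)): flow always
  widens the unstable parameter range, and for very fast flow the criterion
  degenerates to s_nc < 0, independent of both diffusion constants;
* slow-flow limit: sigma(q) ~ sigma0(q) + i vf q^2 A(q) with A(q) > 0 on the
  unstable band (upstream propagation at first order in vf);
* fast-flow limit: sigma(q) ~ fm - Dm q^2 + i fc fm / (vf q), so the growth
  rate loses its dependence on Dc and the drift slows down as 1/vf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .kinetics import HomogeneousState, ReactionParams, homogeneous_state

logger = logging.getLogger(__name__)

__all__ = [
    "FlowProfile",
    "SystemParams",
    "DispersionResult",
    "dispersion",
    "dispersion_relation",
    "unstable_band",
    "instability_criterion",
    "long_wavelength_sigma",
    "long_wavelength_phase_velocity",
    "slow_flow_coefficient",
    "fast_flow_sigma",
    "eigenvector_phase",
]


@dataclass(frozen=True)
class FlowProfile:
    """Cytosolic flow field, uniform or parabolic, switchable in time.

    ``kind='uniform'`` is a constant signed speed ``vf``; ``kind='parabolic'``
    is ``vmax * (1 - 4*(x/L - 1/2)**2)``, vanishing at both walls (the minimal
    model of a cortical flow that respects no-flux boundaries).  The flow is
    identically zero before the onset time ``t0`` and, if ``t_off`` is set,
    again after ``t_off``.
    """

    kind: str = "uniform"
    vf: float = 0.0
    vmax: float = 0.0
    t0: float = 0.0
    t_off: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "parabolic"):
            raise ValueError(f"unknown flow kind {self.kind!r}")
        if self.t_off is not None and self.t_off < self.t0:
            raise ValueError("t_off must not precede t0")

    @property
    def is_uniform(self) -> bool:
        return self.kind == "uniform"

    def speed(self, x, L: float):
        """Flow speed at positions x (after onset; time gating is the
        integrator's job)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "uniform":
            return np.full_like(x, self.vf)
        return self.vmax * (1.0 - 4.0 * (x / L - 0.5) ** 2)

    def active(self, t: float) -> bool:
        if t < self.t0:
            return False
        return self.t_off is None or t < self.t_off


@dataclass(frozen=True)
class SystemParams:
    """Transport constants, domain and reaction parameters of one system.

    Defaults are the canonical operating point of the model: slow membrane
    diffusion Dm = 0.01 um^2/s, fast cytosolic diffusion Dc = 10 um^2/s,
    mean total density n_bar = 5 /um on a periodic domain of length 10 um.
    """

    Dm: float = 0.01
    Dc: float = 10.0
    L: float = 10.0
    boundary: str = "periodic"
    n_bar: float = 5.0
    flow: FlowProfile = field(default_factory=FlowProfile)
    reaction: ReactionParams = field(default_factory=ReactionParams)

    def __post_init__(self) -> None:
        if self.Dm < 0 or self.Dc < 0:
            raise ValueError("diffusion constants must be non-negative")
        if self.L <= 0:
            raise ValueError("domain length must be positive")
        if self.boundary not in ("periodic", "no-flux"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.n_bar < 0:
            raise ValueError("mean total density must be non-negative")

    def steady_state(self) -> HomogeneousState:
        return homogeneous_state(self.n_bar, self.reaction)

    def with_flow(self, **kw) -> "SystemParams":
        return replace(self, flow=replace(self.flow, **kw))


@dataclass(frozen=True)
class DispersionResult:
    """Dominant dispersion branch on a wavenumber grid, plus band summary.

    ``sigma`` is the branch with the larger real part at each q,
    ``sigma_minor`` the other one.  ``q_max`` is the right edge of the band
    of growing modes, ``q_star`` the fastest-growing mode and ``lambda_star``
    its wavelength; all three are NaN when the band is empty.  ``v_phase``
    is the modal drift speed -Im sigma / q (NaN at q = 0).
    """

    q_grid: np.ndarray
    sigma: np.ndarray
    sigma_minor: np.ndarray
    q_max: float
    q_star: float
    lambda_star: float
    v_phase: np.ndarray

    @property
    def unstable(self) -> bool:
        return np.isfinite(self.q_max)


def _resolve_vf(sys: SystemParams, vf: float | None) -> float:
    """Uniform flow speed for the linear analysis.

    An explicit ``vf`` is used as-is (the flow profile in ``sys`` is then
    irrelevant to the linearization); ``vf=None`` takes the speed from the
    system's flow profile, which must be uniform -- the linear analysis is
    only defined for constant flow.
    """
    if vf is not None:
        return float(vf)
    if not sys.flow.is_uniform:
        raise ValueError(
            "linear stability is defined for uniform flow only; pass vf "
            "explicitly or use a uniform FlowProfile"
        )
    return float(sys.flow.vf)


def _jacobian(q, state: HomogeneousState, sys: SystemParams, vf: float):
    return np.array(
        [
            [-sys.Dc * q * q - 1j * vf * q - state.fc, -state.fm],
            [state.fc, -sys.Dm * q * q + state.fm],
        ],
        dtype=complex,
    )


def dispersion(q, state: HomogeneousState, sys: SystemParams, vf: float | None = 0.0):
    """Both complex growth rates of mode q; dominant branch first.

    Parameters
    ----------
    q : float or array
        Wavenumber(s), 1/um, q >= 0.
    state : HomogeneousState
        Uniform equilibrium to linearize around.
    sys : SystemParams
        Transport constants (Dm, Dc); the flow profile must be uniform.
    vf : float
        Uniform flow speed (um/s, signed).

    Returns
    -------
    (sigma, sigma_minor) : complex or complex ndarray
        Eigenvalues ordered by real part (ties by imaginary part).
    """
    vf = _resolve_vf(sys, vf)
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q_arr < 0):
        raise ValueError("wavenumbers must be non-negative")
    mats = np.empty((q_arr.size, 2, 2), dtype=complex)
    for i, qi in enumerate(q_arr):
        mats[i] = _jacobian(qi, state, sys, vf)
    ev = np.linalg.eigvals(mats)  # (n, 2)
    # dominant = larger real part; ties broken by larger imaginary part
    order = np.lexsort((ev.imag, ev.real), axis=-1)
    tie = np.abs(ev[:, 0].real - ev[:, 1].real) < 1e-14 * np.maximum(1.0, np.abs(ev).max())
    if np.any(tie):
        logger.debug("dispersion: %d real-part ties broken by imaginary part", int(tie.sum()))
    minor = np.take_along_axis(ev, order[:, :1], axis=1)[:, 0]
    major = np.take_along_axis(ev, order[:, 1:], axis=1)[:, 0]
    if np.isscalar(q) or np.ndim(q) == 0:
        return complex(major[0]), complex(minor[0])
    return major, minor


def eigenvector_phase(q, state: HomogeneousState, sys: SystemParams, vf: float | None = 0.0):
    """Phase lag of the cytosolic component relative to the membrane one.

    For the dominant eigenvector (c_hat, m_hat) of mode q, returns
    arg(c_hat / m_hat) in radians.  Without flow the two components are in
    (anti)phase; flow introduces a lag that grows with |vf| and saturates at
    large flow speed.  The saturation value is a diagnostic output, not an
    assumption.
    """
    vf = _resolve_vf(sys, vf)
    J = _jacobian(float(q), state, sys, vf)
    w, v = np.linalg.eig(J)
    order = np.lexsort((w.imag, w.real))
    vec = v[:, order[1]]  # dominant
    c_hat, m_hat = vec[0], vec[1]
    return float(np.angle(c_hat / m_hat))


def instability_criterion(
    state: HomogeneousState, sys: SystemParams, vf: float = 0.0
) -> tuple[bool, float]:
    """Flow-modified slope criterion for the mass-redistribution instability.

    The uniform state is laterally unstable iff the nullcline slope satisfies
    s_nc < threshold with

        threshold = -Dm / (Dc + vf^2 / (fc (1 + s_nc)^2)),

    the long-wavelength band-opening condition (the sign of the q^2
    coefficient of the expansion in :func:`long_wavelength_sigma`).  Without
    flow this is the
    diffusive criterion s_nc < -Dm/Dc; as |vf| grows the threshold rises
    monotonically towards 0^-, so flow always widens the unstable range, and
    the Dc = 0 case remains well defined whenever vf != 0.

    Returns ``(unstable, threshold)``.
    """
    if state.sigma1 >= 0:
        raise ValueError(
            "criterion applies to homogeneously stable states (sigma1 < 0)"
        )
    if sys.Dc == 0.0 and vf == 0.0:
        raise ValueError("criterion undefined for Dc = 0 without flow")
    denom = sys.Dc + vf * vf / (state.fc * (1.0 + state.s_nc) ** 2)
    threshold = -sys.Dm / denom
    return bool(state.s_nc < threshold), float(threshold)


def _q_scale_guess(state: HomogeneousState, sys: SystemParams, vf: float) -> float:
    """Upper estimate of the band edge used to size search grids.

    The growth rate is bounded above by fm - Dm q^2 (fast-cytosol envelope),
    so the band cannot extend beyond sqrt(fm/Dm) when fm > 0.
    """
    if state.fm > 0 and sys.Dm > 0:
        return float(np.sqrt(state.fm / sys.Dm))
    # no positive reactive feedback: fall back to a reaction-diffusion scale
    rate = max(abs(state.fm), state.fc, 1e-6)
    D = max(sys.Dm, 1e-6)
    return float(np.sqrt(rate / D))


def _composite_q_grid(q_hi: float, n: int = 512) -> np.ndarray:
    """Logarithmic-plus-linear grid on (0, q_hi]; resolves both the q->0
    opening of the band and its right edge."""
    n_log = n // 4
    log_part = np.geomspace(q_hi * 1e-6, q_hi * 0.05, n_log)
    lin_part = np.linspace(q_hi * 0.05, q_hi, n - n_log)
    return np.unique(np.concatenate([log_part, lin_part]))


def unstable_band(
    state: HomogeneousState, sys: SystemParams, vf: float | None = 0.0
) -> tuple[float, float, float]:
    """Band of growing modes: (q_max, q_star, lambda_star).

    q_max is the right edge of the band where Re sigma crosses zero (bracketed
    root solve), q_star the fastest-growing mode (bounded maximization) and
    lambda_star = 2 pi / q_star.  Returns (nan, nan, nan) when no mode grows.
    """
    vf = _resolve_vf(sys, vf)

    def re_sigma(q):
        return dispersion(float(q), state, sys, vf)[0].real

    q_hi = 4.0 * _q_scale_guess(state, sys, vf)
    grid = _composite_q_grid(q_hi)
    vals = np.array([re_sigma(q) for q in grid])
    pos = vals > 0
    if not np.any(pos):
        return (float("nan"),) * 3
    i_last = np.max(np.nonzero(pos))
    if i_last == len(grid) - 1:
        # extend until the envelope argument guarantees decay
        q_right = grid[-1]
        while re_sigma(q_right) > 0 and q_right < 1e6:
            q_right *= 2.0
        if re_sigma(q_right) > 0:
            raise RuntimeError("failed to bracket the band edge")
    else:
        q_right = grid[i_last + 1]
    q_left = grid[i_last]
    q_max = brentq(re_sigma, q_left, q_right, xtol=1e-10)
    res = minimize_scalar(
        lambda q: -re_sigma(q), bounds=(q_max * 1e-6, q_max), method="bounded",
        options={"xatol": 1e-10},
    )
    q_star = float(res.x)
    return float(q_max), q_star, float(2.0 * np.pi / q_star)


def dispersion_relation(
    state: HomogeneousState,
    sys: SystemParams,
    vf: float = 0.0,
    q_grid=None,
    n_q: int = 512,
) -> DispersionResult:
    """Dominant dispersion branch sampled on a grid, with band summary."""
    vf = _resolve_vf(sys, vf)
    band = unstable_band(state, sys, vf)
    q_max = band[0]
    if q_grid is None:
        q_hi = 4.0 * (q_max if np.isfinite(q_max) else _q_scale_guess(state, sys, vf))
        q_grid = np.concatenate([[0.0], _composite_q_grid(q_hi, n_q - 1)])
    q_grid = np.asarray(q_grid, dtype=float)
    sigma, sigma_minor = dispersion(q_grid, state, sys, vf)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_phase = np.where(q_grid > 0, -sigma.imag / np.where(q_grid > 0, q_grid, 1.0), np.nan)
    return DispersionResult(
        q_grid=q_grid,
        sigma=sigma,
        sigma_minor=sigma_minor,
        q_max=band[0],
        q_star=band[1],
        lambda_star=band[2],
        v_phase=v_phase,
    )


def long_wavelength_sigma(q, state: HomogeneousState, sys: SystemParams, vf: float = 0.0):
    """Second-order small-q expansion of the dominant growth rate.

    sigma(q) ~ -(1 + s_nc)^-1 * [ i s_nc vf q + (Dm + s_nc Dc) q^2
                                  + s_nc vf^2 / (fc (1 + s_nc)^2) q^2 ].

    Valid for s_nc > -1 (homogeneously stable states).  The q-linear
    imaginary term gives the wavelength-independent long-wave phase velocity
    vf * s_nc / (1 + s_nc).
    """
    s = state.s_nc
    if s <= -1:
        raise ValueError("expansion requires s_nc > -1")
    q = np.asarray(q, dtype=float)
    pref = -1.0 / (1.0 + s)
    return pref * (
        1j * s * vf * q
        + (sys.Dm + s * sys.Dc) * q * q
        + s * vf * vf / (state.fc * (1.0 + s) ** 2) * q * q
    )


def long_wavelength_phase_velocity(state: HomogeneousState, vf: float) -> float:
    """Drift speed of long-wavelength modes, vf * s_nc / (1 + s_nc)."""
    return vf * state.s_nc / (1.0 + state.s_nc)


def slow_flow_coefficient(
    q, state: HomogeneousState, sys: SystemParams, vf_eps: float = 1e-3
):
    """First-order flow response A(q) of the dispersion relation.

    For slow flow sigma(q; vf) ~ sigma(q; 0) + i vf q^2 A(q).  A(q) is
    evaluated numerically as the symmetric difference
    [Im sigma(q; +vf_eps) - Im sigma(q; -vf_eps)] / (2 vf_eps q^2); it is
    positive wherever the no-flow growth rate is positive, which is the
    linear-order statement that growing modes drift upstream.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("A(q) is defined for q > 0")
    sig_p, _ = dispersion(q, state, sys, +vf_eps)
    sig_m, _ = dispersion(q, state, sys, -vf_eps)
    return (np.imag(sig_p) - np.imag(sig_m)) / (2.0 * vf_eps * q * q)


def fast_flow_sigma(q, state: HomogeneousState, sys: SystemParams, vf: float):
    """Fast-flow limit of the dominant branch, fm - Dm q^2 + i fc fm/(vf q).

    The real part no longer involves Dc or vf: with near-instantaneous
    cytosolic transport the growth rate is set by membrane processes alone.
    The implied drift speed -fc fm/(vf q^2) decays as 1/vf.
    """
    if vf == 0:
        raise ValueError("fast-flow limit requires vf != 0")
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("fast-flow limit is defined for q > 0")
    return state.fm - sys.Dm * q * q + 1j * state.fc * state.fm / (vf * q)


def fast_flow_phase_velocity(q, state: HomogeneousState, vf: float):
    """Drift speed in the fast-flow limit, -fc fm / (vf q^2)."""
    q = np.asarray(q, dtype=float)
    return -state.fc * state.fm / (vf * q * q)
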