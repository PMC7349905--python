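"""Pattern diagnostics: peak tracking, phase-plane geometry, classification.

These post-processing analyses quantify the nonlinear behaviour of the
model: how fast a membrane peak drifts under cytosolic flow and in which
direction, how the pattern's phase-plane trajectory opens from the
flux-balance line into a loop, whether a steady pattern is a mesa or a peak,
and where in a non-uniform system the local total density enters the
laterally unstable range (regional mass-redistribution instability).

Key geometric objects (phase plane of membrane vs cytosol concentration):

* the reactive nullcline f(m, c) = 0;
* the flux-balance subspace (FBS), the line of slope -Dm/Dc that contains
  every stationary no-flow pattern;
* the loop a flowing pattern traces instead, whose nullcline crossings cL
  (upstream flank) and cR (downstream flank) measure the attachment
  asymmetry that propels the peak: v_p is proportional to cL - cR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinetics import (
    HomogeneousState,
    ReactionParams,
    homogeneous_state,
    nullcline_c,
    reaction_partials,
)
from .stability import SystemParams, dispersion, instability_criterion, unstable_band
from .dynamics import ConcentrationField, SimulationResult

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTrack",
    "PhasePlaneTrajectory",
    "PatternClassification",
    "track_peak",
    "phase_trajectory",
    "inflection_state",
    "predict_vp_lsa",
    "classify_pattern",
    "unstable_density_range",
    "regional_instability",
]


# ---------------------------------------------------------------- peak tracking

@dataclass
class PeakTrack:
    """Sub-grid peak trajectory and its fitted drift speed.

    ``v_p`` is the least-squares slope of position vs time; it is NaN when
    the window holds more than one dominant peak or the instantaneous speed
    is not steady (relative spread above ``steady_rtol``).
    """

    times: np.ndarray
    positions: np.ndarray  # unwrapped (may leave [0, L))
    v_p: float
    v_p_stderr: float
    steady: bool
    n_peaks: int


def _parabolic_peak(x: np.ndarray, m: np.ndarray, L: float, periodic: bool) -> float:
    """Sub-grid maximum via a parabola through argmax and its neighbours."""
    N = m.size
    i = int(np.argmax(m))
    if periodic:
        ml, mc, mr = m[(i - 1) % N], m[i], m[(i + 1) % N]
    else:
        if i == 0 or i == N - 1:
            return float(x[i])
        ml, mc, mr = m[i - 1], m[i], m[i + 1]
    denom = ml - 2.0 * mc + mr
    delta = 0.0 if denom == 0 else 0.5 * (ml - mr) / denom
    dx = x[1] - x[0]
    pos = x[i] + delta * dx
    return float(pos % L) if periodic else float(pos)


def _count_peaks(m: np.ndarray, periodic: bool, rel_height: float = 0.5) -> int:
    """Dominant local maxima: above min + rel_height * amplitude."""
    amp = m.max() - m.min()
    if amp <= 0:
        return 0
    thresh = m.min() + rel_height * amp
    mm = np.concatenate([m[-1:], m, m[:1]]) if periodic else np.concatenate([[m[0]], m, [m[-1]]])
    is_max = (mm[1:-1] >= mm[:-2]) & (mm[1:-1] > mm[2:]) & (mm[1:-1] > thresh)
    return int(np.count_nonzero(is_max))


def track_peak(
    result: SimulationResult,
    window: tuple[float, float] | None = None,
    steady_rtol: float = 0.02,
) -> PeakTrack:
    """Track the dominant membrane peak and fit its drift speed.

    Positions are located by parabolic interpolation through the maximum and
    unwrapped across the periodic boundary; v_p is the slope of a straight
    line fitted over the window, reported with the fit's residual standard
    error.  Steady propagation requires the relative spread of the
    instantaneous speed to stay below ``steady_rtol`` (an absolute floor of
    1e-5 um/s covers stationary patterns).
    """
    L = result.params.L
    periodic = result.params.boundary == "periodic"
    if window is None:
        sel = np.ones(result.times.size, dtype=bool)
    else:
        sel = (result.times >= window[0]) & (result.times <= window[1])
    times = result.times[sel]
    if times.size < 3:
        raise ValueError("window holds fewer than three saved frames")
    frames = result.m[sel]
    raw = np.array([_parabolic_peak(result.x, mi, L, periodic) for mi in frames])
    if periodic:
        jumps = np.diff(raw)
        jumps -= L * np.round(jumps / L)
        pos = raw[0] + np.concatenate([[0.0], np.cumsum(jumps)])
    else:
        pos = raw
    n_peaks = max(_count_peaks(mi, periodic) for mi in frames)
    speeds = np.diff(pos) / np.diff(times)
    mean_v = speeds.mean()
    spread = speeds.std()
    steady = bool(spread < max(steady_rtol * abs(mean_v), 1e-5))
    if n_peaks > 1 or not steady:
        logger.warning(
            "track_peak: v_p withheld (n_peaks=%d, steady=%s, spread=%.2e, mean=%.2e)",
            n_peaks, steady, spread, mean_v,
        )
        return PeakTrack(times, pos, float("nan"), float("nan"), steady, n_peaks)
    A = np.vstack([times, np.ones_like(times)]).T
    coef, res_, *_ = np.linalg.lstsq(A, pos, rcond=None)
    v_p = float(coef[0])
    dof = max(times.size - 2, 1)
    s2 = float(res_[0]) / dof if res_.size else 0.0
    stderr = float(np.sqrt(s2 / np.sum((times - times.mean()) ** 2)))
    return PeakTrack(times, pos, v_p, stderr, steady, n_peaks)


# ------------------------------------------------------------ phase-plane loop

@dataclass
class PhasePlaneTrajectory:
    """Pattern trajectory in the (m, c) phase plane.

    ``loop_area`` is the signed shoelace area of the closed x-ordered point
    sequence; it vanishes (with the points collinear on the FBS) for
    stationary no-flow patterns and opens up under flow.  ``cL``/``cR`` are
    the cytosolic concentrations where the trajectory crosses the reactive
    nullcline on the upstream/downstream flank of the peak.
    """

    m: np.ndarray
    c: np.ndarray
    loop_area: float
    cL: float
    cR: float
    mL: float
    mR: float
    fbs_slope: float
    fbs_offset: float
    fbs_max_distance: float  # max normal distance from best-fit FBS line


def _nullcline_crossings(field: ConcentrationField, p: ReactionParams):
    """(x, m, c) of every sign change of c - c_nullcline(m), by linear
    interpolation between adjacent cells."""
    g = field.c - nullcline_c(field.m, p)
    out = []
    for i in range(g.size - 1):
        a, b = g[i], g[i + 1]
        if a == 0.0:
            out.append((field.x[i], field.m[i], field.c[i]))
        elif a * b < 0:
            w = a / (a - b)
            out.append(
                (
                    field.x[i] + w * (field.x[i + 1] - field.x[i]),
                    field.m[i] + w * (field.m[i + 1] - field.m[i]),
                    field.c[i] + w * (field.c[i + 1] - field.c[i]),
                )
            )
    return out


def phase_trajectory(
    field: ConcentrationField,
    p: ReactionParams,
    sys: SystemParams,
    vf: float | None = None,
) -> PhasePlaneTrajectory:
    """Phase-plane loop of a single-peak snapshot.

    The flank of each nullcline crossing is decided relative to the peak
    position and the flow direction (``vf`` defaults to the system's uniform
    flow speed): for vf > 0 the upstream flank is the smaller-x side.  Among
    multiple crossings on a flank the one closest to the peak (largest m) is
    used.  Raises a diagnostic error when the trajectory crosses the
    nullcline fewer than twice (pattern too weak to define a loop).
    """
    if vf is None:
        vf = sys.flow.vf if sys.flow.is_uniform else 0.0
    L = sys.L
    periodic = sys.boundary == "periodic"
    x_peak = _parabolic_peak(field.x, field.m, L, periodic)
    crossings = _nullcline_crossings(field, p)
    if len(crossings) < 2:
        raise RuntimeError(
            f"only {len(crossings)} nullcline crossing(s): pattern too weak "
            "for a phase-plane loop"
        )

    def signed_offset(x):
        d = x - x_peak
        if periodic:
            d -= L * np.round(d / L)
        return d

    left = [cr for cr in crossings if signed_offset(cr[0]) < 0]
    right = [cr for cr in crossings if signed_offset(cr[0]) >= 0]
    if not left or not right:
        raise RuntimeError("no nullcline crossing on one flank of the peak")
    pick = lambda side: max(side, key=lambda cr: cr[1])  # closest to peak in m
    lx, lm, lc = pick(left)
    rx, rm, rc = pick(right)
    if vf >= 0:
        (mL, cL), (mR, cR) = (lm, lc), (rm, rc)
    else:
        (mL, cL), (mR, cR) = (rm, rc), (lm, lc)

    m, c = field.m, field.c
    # shoelace over the x-ordered closed polygon
    area = 0.5 * float(np.sum(m * np.roll(c, -1) - np.roll(m, -1) * c))
    slope = -sys.Dm / sys.Dc
    offset = float(np.mean(c - slope * m))
    dist = np.abs(c - (offset + slope * m)) / np.sqrt(1.0 + slope * slope)
    return PhasePlaneTrajectory(
        m=m.copy(),
        c=c.copy(),
        loop_area=area,
        cL=float(cL),
        cR=float(cR),
        mL=float(mL),
        mR=float(mR),
        fbs_slope=slope,
        fbs_offset=offset,
        fbs_max_distance=float(dist.max()),
    )


# -------------------------------------------------- linear-stability prediction

def _fbs_nullcline_intersections(offset: float, slope: float, p: ReactionParams, m_hi: float):
    """All m where the FBS line c = offset + slope*m meets the nullcline."""

    def h(m):
        return nullcline_c(m, p) - (offset + slope * m)

    grid = np.linspace(0.0, m_hi, 4001)
    vals = h(grid)
    roots = []
    for i in range(grid.size - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=1e-12))
    return sorted(roots)


def inflection_state(
    field: ConcentrationField, p: ReactionParams, sys: SystemParams
) -> HomogeneousState:
    """Local reactive equilibrium at the pattern's inflection point.

    For a stationary no-flow pattern the inflection point sits at the middle
    intersection of the flux-balance line with the reactive nullcline; the
    returned state carries the linearization evaluated exactly there (which
    may lie on a nullcline branch other than the one connected to the
    origin, so it is built from the point, not from a root search in n).
    """
    slope = -sys.Dm / sys.Dc
    offset = float(np.mean(field.c - slope * field.m))
    roots = _fbs_nullcline_intersections(offset, slope, p, m_hi=1.5 * float(field.m.max()))
    if len(roots) < 2:
        raise RuntimeError(
            f"found {len(roots)} FBS-nullcline intersection(s); need at least 2"
        )
    m_i = roots[1]  # middle intersection: the laterally unstable composition
    c_i = float(nullcline_c(m_i, p))
    fm, fc = reaction_partials(m_i, c_i, p)
    fm, fc = float(fm), float(fc)
    return HomogeneousState(
        n_bar=m_i + c_i, m_star=m_i, c_star=c_i, fm=fm, fc=fc,
        s_nc=-fm / fc, sigma1=fm - fc,
    )


def predict_vp_lsa(state: HomogeneousState, sys: SystemParams, vf: float) -> float:
    """Peak speed predicted from linear theory at the inflection composition.

    The relevant mode for a fully formed peak is the shortest unstable one,
    q_max (its wavelength matches the peak width), so the prediction is the
    phase velocity -Im sigma(q_max)/q_max of that mode.  Returns NaN when
    the band is empty at the given composition.
    """
    q_max, _, _ = unstable_band(state, sys, vf)
    if not np.isfinite(q_max):
        logger.warning("predict_vp_lsa: empty unstable band, prediction undefined")
        return float("nan")
    sig, _ = dispersion(q_max, state, sys, vf)
    return float(-sig.imag / q_max)


# -------------------------------------------------------------- classification

@dataclass
class PatternClassification:
    """Mesa/peak/homogeneous label with the underlying measurements.

    A mesa has a high plateau at least ``plateau_factor`` times wider than
    the 10-90% interface rise distance; a peak is two interfaces back to
    back, with no resolved plateau between them.
    """

    label: str  # 'homogeneous' | 'mesa' | 'peak'
    amplitude: float
    plateau_fraction: float
    interface_width: float
    plateau_width: float


def _runs_above(mask: np.ndarray, periodic: bool) -> int:
    """Length (cells) of the longest contiguous True run, with wraparound."""
    if mask.all():
        return mask.size
    if not mask.any():
        return 0
    if periodic:
        i0 = int(np.argmin(mask))  # rotate so a False sits first
        mask = np.roll(mask, -i0)
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def classify_pattern(
    field: ConcentrationField,
    p: ReactionParams,
    sys: SystemParams,
    homog_rtol: float = 1e-3,
    top_band: float = 0.05,
    plateau_factor: float = 1.5,
) -> PatternClassification:
    """Classify a steady-state membrane profile as homogeneous, mesa or peak.

    Thresholds (all configurable): homogeneous when the amplitude is below
    ``homog_rtol * n_bar``; the high plateau is the set of cells within
    ``top_band`` of the amplitude below the maximum; a mesa requires that
    plateau to span at least ``plateau_factor`` interface widths.  The
    default factor 1.5 separates the two shapes cleanly for smooth kinetics:
    a pure curvature cap (two interfaces back to back) yields a top-band /
    rise-distance ratio of about 0.6, while a profile pinned at the third
    flux-balance--nullcline intersection exceeds 2.
    """
    m = field.m
    amp = float(m.max() - m.min())
    n_bar = float(field.n.mean())
    periodic = sys.boundary == "periodic"
    dx = field.dx
    if amp < homog_rtol * n_bar:
        return PatternClassification("homogeneous", amp, 1.0, 0.0, float(sys.L))

    # interface width: 10-90% rise distance, averaged over the two flanks
    # of the dominant peak (profile rotated so the maximum is centered)
    N = m.size
    i_max = int(np.argmax(m))
    mm = np.roll(m, N // 2 - i_max) if periodic else m
    lo, hi = m.min() + 0.1 * amp, m.min() + 0.9 * amp

    def crossing(profile: np.ndarray, level: float, from_end: bool) -> float | None:
        idx = range(profile.size - 1)
        it = reversed(list(idx)) if from_end else idx
        for i in it:
            a, b = profile[i] - level, profile[i + 1] - level
            if a == 0.0:
                return float(i)
            if a * b < 0:
                return i + a / (a - b)
        return None

    j_max = int(np.argmax(mm))
    left, right = mm[: j_max + 1], mm[j_max:]
    widths = []
    lo_l, hi_l = crossing(left, lo, from_end=True), crossing(left, hi, from_end=True)
    if lo_l is not None and hi_l is not None and hi_l >= lo_l:
        widths.append((hi_l - lo_l) * dx)
    lo_r = crossing(right[::-1], lo, from_end=True)
    hi_r = crossing(right[::-1], hi, from_end=True)
    if lo_r is not None and hi_r is not None and hi_r >= lo_r:
        widths.append((hi_r - lo_r) * dx)
    interface_width = float(np.mean(widths)) if widths else float(dx)

    top = m >= m.max() - top_band * amp
    plateau_cells = _runs_above(top, periodic)
    plateau_width = plateau_cells * dx
    plateau_fraction = plateau_width / sys.L
    label = "mesa" if plateau_width >= plateau_factor * interface_width else "peak"
    return PatternClassification(label, amp, plateau_fraction, interface_width, plateau_width)


# ------------------------------------------------- regional lateral instability

def unstable_density_range(
    p: ReactionParams,
    sys: SystemParams,
    vf: float = 0.0,
    n_cap: float | None = None,
    n_scan: int = 400,
) -> tuple[float, float]:
    """Interval (n_minus, n_plus) of total densities that are laterally
    unstable under uniform flow vf.

    Scans the homogeneous-state branch over (0, n_cap] (default 4 * n_bar),
    applies the flow-modified slope criterion pointwise, and refines the
    edges of the maximal contiguous unstable interval by bisection.
    Returns (nan, nan) when no density in the scan is unstable.
    """
    if n_cap is None:
        n_cap = 4.0 * max(sys.n_bar, 1.0)
    grid = np.linspace(n_cap / n_scan, n_cap, n_scan)

    def crit(n: float) -> bool:
        st = homogeneous_state(n, p)
        if st.sigma1 >= 0:
            return False
        return instability_criterion(st, sys, vf)[0]

    def margin(n: float) -> float:
        st = homogeneous_state(n, p)
        if st.sigma1 >= 0:
            return 1.0
        _, thr = instability_criterion(st, sys, vf)
        return st.s_nc - thr  # negative inside the unstable range

    flags = np.array([crit(n) for n in grid])
    if not flags.any():
        return float("nan"), float("nan")
    # maximal contiguous run of True
    best_len, best_start, cur_len, cur_start = 0, 0, 0, 0
    for i, v in enumerate(flags):
        if v:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    i0, i1 = best_start, best_start + best_len - 1
    n_minus = grid[i0]
    if i0 > 0:
        n_minus = brentq(margin, grid[i0 - 1], grid[i0], xtol=1e-10)
    n_plus = grid[i1]
    if i1 < grid.size - 1:
        n_plus = brentq(margin, grid[i1], grid[i1 + 1], xtol=1e-10)
    return float(n_minus), float(n_plus)


def regional_instability(
    field: ConcentrationField,
    p: ReactionParams,
    sys: SystemParams,
    density_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, bool]:
    """Mark cells whose local total density is laterally unstable (no-flow
    criterion, the one governing the self-organized stage) and decide
    whether the instability is actually triggered.

    The trigger requires a contiguous marked region wider than the shortest
    unstable wavelength 2*pi/q_max evaluated at the region's mean
    composition: narrower regions cannot host a growing mode.

    ``density_range`` may pass a precomputed (n_minus, n_plus) to avoid
    re-scanning the density axis when classifying many frames of one run.
    """
    if density_range is None:
        n_loc_max = float(np.max(field.n))
        n_cap = max(4.0 * max(sys.n_bar, 1.0), 1.5 * n_loc_max)
        density_range = unstable_density_range(p, sys, vf=0.0, n_cap=n_cap)
    n_minus, n_plus = density_range
    n_loc = field.n
    if not np.isfinite(n_minus):
        return np.zeros(n_loc.size, dtype=bool), False
    mask = (n_loc >= n_minus) & (n_loc <= n_plus)
    if not mask.any():
        return mask, False
    periodic = sys.boundary == "periodic"
    # widest contiguous marked region
    run = _runs_above(mask, periodic)
    width = run * field.dx
    st = homogeneous_state(float(n_loc[mask].mean()), p)
    q_max, _, _ = unstable_band(st, sys, vf=0.0)
    if not np.isfinite(q_max):
        return mask, False
    triggered = bool(width > 2.0 * np.pi / q_max)
    return mask, triggered
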