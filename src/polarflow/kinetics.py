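"""Reaction kinetics for the two-component mass-conserving polarity model.

A single protein species cycles between a membrane-bound state (concentration
``m``) and a cytosolic state (concentration ``c``).  The net reactive exchange
has the generic attachment--detachment form

    f(m, c) = a(m) * c - d(m) * m,

with ``a(m) > 0`` the attachment rate and ``d(m) > 0`` the detachment rate.
The shipped default kinetics combine basal attachment, self-recruitment and
enzyme-driven (Michaelis--Menten) detachment:

    a(m) = kon + kfb * m,        d(m) = koff / (KD + m).

Because the reactions only exchange protein between the two states, the local
total density ``n = m + c`` has no reactive source; its spatial mean is a
conserved quantity of the full dynamics.  Everything downstream (linear
stability, phase-plane geometry, pattern classification) is built on the
quantities computed here: the reactive nullcline ``f = 0``, the homogeneous
steady state ``(m*, c*)`` at a given mean density, and the linearization
``fm = df/dm``, ``fc = df/dc`` at that state.

Units: lengths in um, times in s, line densities in 1/um.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionParams",
    "HomogeneousState",
    "reaction_rate",
    "reaction_partials",
    "nullcline_c",
    "nullcline_slope",
    "homogeneous_state",
    "local_equilibria",
]


@dataclass(frozen=True)
class ReactionParams:
    """Kinetic constants of the default attachment--detachment kinetics.

    Parameters
    ----------
    kon : float
        Basal attachment rate (1/s).
    kfb : float
        Self-recruitment (positive feedback) rate (um/s).
    koff : float
        Maximal enzyme-driven detachment rate (1/s).
    KD : float
        Michaelis--Menten constant of the detachment enzyme (1/um).
    """

    kon: float = 1.0
    kfb: float = 1.0
    koff: float = 2.0
    KD: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kon", "kfb", "koff", "KD"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"ReactionParams.{name} must be strictly positive, got {value!r}")

    # the (a, d) decomposition keeps the kinetics pluggable: any subclass
    # overriding attach/detach (and their m-derivatives) inherits the rest
    def attach(self, m):
        """Attachment rate a(m) = kon + kfb*m (1/s)."""
        return self.kon + self.kfb * np.asarray(m, dtype=float)

    def detach(self, m):
        """Detachment rate d(m) = koff/(KD + m) (1/s)."""
        m = np.asarray(m, dtype=float)
        return self.koff / (self.KD + m)

    def attach_dm(self, m):
        """da/dm."""
        return np.full_like(np.asarray(m, dtype=float), self.kfb)

    def detach_dm(self, m):
        """dd/dm."""
        m = np.asarray(m, dtype=float)
        return -self.koff / (self.KD + m) ** 2


@dataclass(frozen=True)
class HomogeneousState:
    """A spatially uniform reactive equilibrium and its linearization.

    Attributes
    ----------
    n_bar : float
        Mean total density m* + c* (1/um).
    m_star, c_star : float
        Membrane and cytosolic concentrations at equilibrium (1/um).
    fm, fc : float
        Partial derivatives of the reaction term at the state (1/s).
        For attachment--detachment kinetics fc = a(m*) > 0.
    s_nc : float
        Slope of the reactive nullcline at the state, -fm/fc (dimensionless).
    sigma1 : float
        Growth rate fm - fc of homogeneous (q = 0) perturbations that respect
        mass conservation of the linearized reaction (1/s).
    """

    n_bar: float
    m_star: float
    c_star: float
    fm: float
    fc: float
    s_nc: float
    sigma1: float

    @property
    def homogeneously_stable(self) -> bool:
        """True when uniform perturbations decay (sigma1 < 0, i.e. s_nc > -1)."""
        return self.sigma1 < 0


def _validate_nonnegative(name, value):
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError(f"{name} must be non-negative, got minimum {value.min()!r}")
    return value


def reaction_rate(m, c, p: ReactionParams | None = None):
    """Net attachment flux f(m, c) = a(m)*c - d(m)*m (1/(um*s)).

    Positive values move protein from the cytosol onto the membrane.
    Accepts scalars or arrays (broadcast); negative concentrations are a
    domain error.
    """
    p = p or ReactionParams()
    m = _validate_nonnegative("m", m)
    c = _validate_nonnegative("c", c)
    return p.attach(m) * c - p.detach(m) * m


def reaction_partials(m, c, p: ReactionParams | None = None):
    """Closed-form partials (fm, fc) = (df/dm, df/dc) of the reaction term.

    fm = a'(m)*c - d'(m)*m - d(m),  fc = a(m).
    """
    p = p or ReactionParams()
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    fm = p.attach_dm(m) * c - p.detach_dm(m) * m - p.detach(m)
    fc = p.attach(m) * np.ones_like(c)
    return fm, fc


def nullcline_c(m, p: ReactionParams | None = None, with_slope: bool = False):
    """Cytosolic concentration on the reactive nullcline, c = d(m)*m/a(m).

    Solves f(m, c) = 0 for c at given membrane concentration.  With
    ``with_slope=True`` also returns the analytic slope dc/dm along the
    nullcline, which equals -fm/fc evaluated on the nullcline.
    """
    p = p or ReactionParams()
    m = _validate_nonnegative("m", m)
    c = p.detach(m) * m / p.attach(m)
    if not with_slope:
        return c
    fm, fc = reaction_partials(m, c, p)
    return c, -fm / fc


def nullcline_slope(m, p: ReactionParams | None = None):
    """Slope dc/dm of the reactive nullcline at membrane concentration m."""
    _, slope = nullcline_c(m, p, with_slope=True)
    return slope


def _steady_state_m(n_bar: float, p: ReactionParams) -> float:
    """Membrane concentration of the uniform equilibrium at mean density n_bar.

    Roots of g(m) = a(m)*(n_bar - m) - d(m)*m on [0, n_bar]; the smallest
    positive-m root is returned (the branch continuously connected to the
    origin as n_bar grows).  Multiple roots are possible for strongly
    nonlinear kinetics and are reported with a warning.
    """

    def g(m):
        return p.attach(m) * (n_bar - m) - p.detach(m) * m

    if n_bar == 0.0:
        return 0.0
    # dense scan to bracket every sign change, then polish with brentq
    grid = np.linspace(0.0, n_bar, 2001)
    vals = g(grid)
    roots = [0.0] if abs(vals[0]) < 1e-14 else []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0 and grid[i] not in roots:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16))
    if abs(vals[-1]) < 1e-14:
        roots.append(grid[-1])
    roots = sorted(set(round(r, 13) for r in roots))
    if not roots:
        raise RuntimeError(
            f"no homogeneous steady state bracketed on [0, {n_bar}] for {p}"
        )
    # g(0) = a(0)*n_bar > 0 for n_bar > 0, so m = 0 is never an equilibrium
    # here; still guard against the scan returning a spurious endpoint root
    positive = [r for r in roots if r > 0 or n_bar == 0]
    if not positive:
        positive = roots
    if len(positive) > 1:
        warnings.warn(
            f"multiple homogeneous steady states at n_bar={n_bar}: {positive}; "
            "taking the smallest-m root",
            RuntimeWarning,
            stacklevel=3,
        )
    return positive[0]


def homogeneous_state(n_bar: float, p: ReactionParams | None = None) -> HomogeneousState:
    """Uniform reactive equilibrium (m*, c*) with m* + c* = n_bar.

    The state on the branch continuously connected to (0, 0) is returned,
    together with the closed-form linearization (fm, fc), the nullcline slope
    s_nc = -fm/fc and the homogeneous eigenvalue sigma1 = fm - fc.
    """
    p = p or ReactionParams()
    if not np.isfinite(n_bar) or n_bar < 0:
        raise ValueError(f"n_bar must be non-negative, got {n_bar!r}")
    m_star = _steady_state_m(float(n_bar), p)
    c_star = float(n_bar) - m_star
    fm, fc = reaction_partials(m_star, c_star, p)
    fm, fc = float(fm), float(fc)
    return HomogeneousState(
        n_bar=float(n_bar),
        m_star=m_star,
        c_star=c_star,
        fm=fm,
        fc=fc,
        s_nc=-fm / fc,
        sigma1=fm - fc,
    )


def local_equilibria(n_profile, p: ReactionParams | None = None):
    """Local reactive equilibria m*(n), c*(n) and slope s_nc(n) along a profile.

    The local total density sets the local equilibrium the reactions pull
    towards; this is the pointwise (vectorized) version of
    :func:`homogeneous_state`, staying on the same branch (smallest-m root)
    for every entry so no branch jumping can occur between neighbouring
    points.

    Returns
    -------
    m_star, c_star, s_nc : ndarray
        Arrays matching the shape of ``n_profile``.
    """
    p = p or ReactionParams()
    n = _validate_nonnegative("n_profile", n_profile)
    flat = np.ravel(n)
    m = np.empty_like(flat)
    c = np.empty_like(flat)
    s = np.empty_like(flat)
    # cache: profiles typically contain long runs of equal densities
    seen: dict[float, tuple[float, float, float]] = {}
    for i, ni in enumerate(flat):
        key = float(ni)
        if key not in seen:
            st = homogeneous_state(key, p)
            seen[key] = (st.m_star, st.c_star, st.s_nc)
        m[i], c[i], s[i] = seen[key]
    shape = np.shape(n)
    return m.reshape(shape), c.reshape(shape), s.reshape(shape)
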