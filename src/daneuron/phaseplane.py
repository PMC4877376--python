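"""Phase-plane analysis of the minimal (planar) model.

Nullcline geometry explains the receptor synergy: NMDA flattens the
N-shaped v-nullcline without unfolding it (smaller w-amplitude of the
limit cycle, hence shorter period), whereas AMPA shifts the folded region
and stabilizes the equilibrium — an Andronov–Hopf bifurcation that ends
firing.  This module computes nullclines, locates and classifies
equilibria from the analytic Jacobian, and traces the Hopf boundary in
the (g_a, g_n) conductance plane.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq

from .minimal import MinimalParams, f_cubic, j_kca, j_stim, nmda_conductance, rhs

__all__ = [
    "EquilibriumInfo",
    "NullclineSet",
    "jacobian",
    "nullclines",
    "find_equilibria",
    "hopf_boundary",
    "cycle_extrema",
]

log = logging.getLogger(__name__)


@dataclass
class EquilibriumInfo:
    """An equilibrium with its linearization and classification."""

    v: float
    w: float
    jacobian: np.ndarray  #: 2x2 analytic Jacobian
    eigenvalues: np.ndarray  #: complex pair
    stability: Literal["stable", "unstable"]
    kind: Literal["focus", "node", "saddle"]

    @property
    def location(self) -> tuple[float, float]:
        return (self.v, self.w)


@dataclass
class NullclineSet:
    """Point sets where dv/dt = 0 and dw/dt = 0 over a phase-plane window."""

    v_nullcline: np.ndarray  #: (n, 2) array of (v, w) points
    w_nullcline: np.ndarray  #: (n, 2) array of (v, w) points
    window: tuple[float, float, float, float]  #: (v_min, v_max, w_min, w_max)


def _total_current(v, w, p: MinimalParams):
    return f_cubic(v, p) + j_kca(v, w, p) + j_stim(v, p)


def jacobian(v: float, w: float, p: MinimalParams) -> np.ndarray:
    """Analytic Jacobian of the minimal model at (v, w).

    The recovery function is piecewise; at w = 0 the derivative of the
    w >= 0 branch is used, consistent with the vector-field convention.
    """
    k4 = p.k_ca ** 4
    w4 = w ** 4
    hill = w4 / (w4 + k4)
    dhill = 4.0 * w ** 3 * k4 / (w4 + k4) ** 2
    df = p.a1 * (3.0 * v ** 2 + 2.0 * p.a2 * v + p.a3)
    gn = nmda_conductance(v, p)
    # d/dv of g_n(v): logistic derivative
    e = p.m_block * math.exp(-6.0 * v)
    dgn = p.g_n * 6.0 * e / (1.0 + e) ** 2
    dj_stim = dgn * (p.e_n - v) - gn - p.g_a
    a11 = (df - p.g_kca * hill + dj_stim) / p.c
    a12 = p.g_kca * (p.e_k - v) * dhill / p.c
    if w >= 0:
        a21 = p.eps / p.c
        a22 = 0.0
    else:
        a21 = 0.01 * p.eps / p.c
        a22 = -p.eps / p.c
    return np.array([[a11, a12], [a21, a22]])


def _classify(jac: np.ndarray) -> tuple[np.ndarray, str, str]:
    eig = np.linalg.eigvals(jac)
    if np.iscomplex(eig).any():
        kind = "focus"
        stability = "stable" if eig.real.max() < 0 else "unstable"
    else:
        ev = np.sort(eig.real)
        if ev[0] < 0 < ev[1]:
            kind = "saddle"
            stability = "unstable"
        else:
            kind = "node"
            stability = "stable" if ev[1] < 0 else "unstable"
    return eig, stability, kind


def nullclines(
    p: MinimalParams,
    window: tuple[float, float, float, float] = (-1.2, 0.2, -0.5, 12.0),
    resolution: int = 800,
) -> NullclineSet:
    """Compute both nullclines over a (v, w) window.

    The v-nullcline solves ``f + j_kca + j_stim = 0`` for w at each v by
    closed-form inversion of the Hill sigmoid: with
    ``h = (f + j_stim) / (g_kca (v - e_k))``, a w >= 0 solution
    ``w = k_ca (h/(1-h))^{1/4}`` exists where 0 <= h < 1, and its mirror
    ``-w`` solves the same equation (the Hill term is even in w).  The
    w-nullcline is the vertical line v = k_w for w >= 0 plus the shallow
    line w = 0.01 (v - k_w) for w < 0.
    """
    v_lo, v_hi, w_lo, w_hi = window
    if not (v_hi > v_lo and w_hi > w_lo):
        raise ValueError(f"empty phase-plane window {window}")
    vv = np.linspace(v_lo, v_hi, resolution)
    pts = []
    for v in vv:
        denom = p.g_kca * (v - p.e_k)
        if denom == 0:
            continue
        h = (f_cubic(v, p) + j_stim(v, p)) / denom
        if 0.0 <= h < 1.0:
            w = p.k_ca * (h / (1.0 - h)) ** 0.25
            if w_lo <= w <= w_hi:
                pts.append((v, w))
            if w_lo <= -w <= w_hi and w > 0:
                pts.append((v, -w))
    v_null = np.array(pts) if pts else np.empty((0, 2))

    wpts = []
    if w_hi > 0 and v_lo <= p.k_w <= v_hi:
        for w in np.linspace(max(w_lo, 0.0), w_hi, resolution):
            wpts.append((p.k_w, w))
    for v in vv[vv < p.k_w]:
        w = 0.01 * (v - p.k_w)
        if w_lo <= w < 0:
            wpts.append((v, w))
    w_null = np.array(wpts) if wpts else np.empty((0, 2))
    return NullclineSet(v_null, w_null, window)


def find_equilibria(
    p: MinimalParams,
    window: tuple[float, float, float, float] = (-1.2, 0.2, -0.5, 30.0),
    n_scan: int = 2000,
) -> list[EquilibriumInfo]:
    """All isolated equilibria of the minimal model in the window.

    Equilibria with w >= 0 lie on the vertical branch v = k_w of the
    w-nullcline, so they are roots of the scalar total current there;
    equilibria with w < 0 lie on w = 0.01 (v - k_w) and are found by a
    scan-and-bisect over v.  Each root is classified from the analytic
    Jacobian.
    """
    v_lo, v_hi, w_lo, w_hi = window
    out: list[EquilibriumInfo] = []

    def _push(v, w):
        jac = jacobian(v, w, p)
        eig, stability, kind = _classify(jac)
        out.append(EquilibriumInfo(v, w, jac, eig, stability, kind))

    if v_lo <= p.k_w <= v_hi:
        ww = np.linspace(max(0.0, w_lo), w_hi, n_scan)
        fw = np.array([_total_current(p.k_w, w, p) for w in ww])
        sign_change = np.nonzero(np.diff(np.sign(fw)) != 0)[0]
        for i in sign_change:
            w_star = brentq(
                lambda w: _total_current(p.k_w, w, p), ww[i], ww[i + 1],
                xtol=1e-14,
            )
            _push(p.k_w, w_star)

    if w_lo < 0:
        vv = np.linspace(v_lo, min(v_hi, p.k_w), n_scan)

        def res(v):
            return _total_current(v, 0.01 * (v - p.k_w), p)

        fv = np.array([res(v) for v in vv])
        sign_change = np.nonzero(np.diff(np.sign(fv)) != 0)[0]
        for i in sign_change:
            v_star = brentq(res, vv[i], vv[i + 1], xtol=1e-14)
            w_star = 0.01 * (v_star - p.k_w)
            if w_star < 0 and w_lo <= w_star:
                _push(v_star, w_star)
    return out


def _upper_equilibrium_w(p: MinimalParams, w_max: float = 1e3) -> Optional[float]:
    """w-coordinate of the (unique) equilibrium on v = k_w, or None.

    The total current at v = k_w is strictly decreasing in w (the SK term
    is the only w-dependence and v = k_w > e_k), so at most one root
    exists; it does when the current at w = 0 is non-negative.
    """
    f0 = _total_current(p.k_w, 0.0, p)
    if f0 < 0:
        return None
    f_inf = _total_current(p.k_w, w_max, p)
    if f_inf > 0:
        return None  # SK cannot balance the drive even at saturation
    return brentq(lambda w: _total_current(p.k_w, w, p), 0.0, w_max, xtol=1e-14)


def _max_real_part(p: MinimalParams) -> Optional[float]:
    w_star = _upper_equilibrium_w(p)
    if w_star is None:
        return None
    eig = np.linalg.eigvals(jacobian(p.k_w, w_star, p))
    return float(eig.real.max())


def hopf_boundary(
    p: MinimalParams,
    ga_values: np.ndarray,
    gn_range: tuple[float, float] = (0.0, 1.2),
    tol: float = 1e-4,
    n_scan: int = 121,
) -> np.ndarray:
    """Trace the oscillation-onset (Hopf) curve in the (g_a, g_n) plane.

    For each g_a the g_n at which the leading eigenvalue's real part of
    the w >= 0 equilibrium changes sign is located by bisection.  Points
    where no sign change exists in the range (equilibrium already
    unstable, or stable throughout) are omitted with a log notice.
    Returns an (n, 2) array of (g_a, g_n) boundary points.
    """
    lo, hi = gn_range
    if hi <= lo or np.any(np.asarray(ga_values) < 0):
        raise ValueError("conductance ranges must be positive")
    pts = []
    gn_grid = np.linspace(lo, hi, n_scan)
    for ga in np.asarray(ga_values, dtype=float):
        vals = np.array(
            [
                _max_real_part(p.replace(g_a=ga, g_n=gn)) or np.nan
                for gn in gn_grid
            ]
        )
        ok = ~np.isnan(vals)
        sgn = np.sign(vals[ok])
        idx = np.nonzero(np.diff(sgn) != 0)[0]
        if len(idx) == 0:
            log.info("no Hopf crossing for g_a=%g in g_n range %s", ga, gn_range)
            continue
        i = idx[0]
        g1, g2 = gn_grid[ok][i], gn_grid[ok][i + 1]
        gn_star = brentq(
            lambda gn: _max_real_part(p.replace(g_a=ga, g_n=gn)),
            g1,
            g2,
            xtol=tol,
        )
        pts.append((ga, gn_star))
    return np.array(pts) if pts else np.empty((0, 2))


def cycle_extrema(
    p: MinimalParams,
    duration: float = 30.0,
    transient: float = 10.0,
    settings=None,
):
    """Attractor extrema (v_min, v_max, w_min, w_max) from simulation.

    Used for one-parameter bifurcation diagrams: near a supercritical
    Hopf point the extrema collapse continuously onto the equilibrium
    branch.
    """
    from .dynamics import SolverSettings, simulate

    traj = simulate(
        "minimal", p, duration=duration, settings=settings or SolverSettings()
    )
    mask = traj.times >= transient
    v = traj.states[mask, 0]
    w = traj.states[mask, 1]
    return float(v.min()), float(v.max()), float(w.min()), float(w.max())
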