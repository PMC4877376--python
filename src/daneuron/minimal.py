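"""Minimal dopaminergic-neuron model.

A planar FitzHugh–Nagumo-type oscillator in which the linear recovery
feedback of the classical FHN system is replaced by the nonlinearity of an
SK-type calcium-activated potassium current.  The fast variable ``v`` plays
the role of membrane potential and the slow variable ``w`` the role of
intracellular calcium concentration; both are dimensionless.  Tonic
glutamatergic input enters through two conductances: a voltage-independent
AMPA-receptor term ``g_a`` and an NMDA-receptor term ``g_n`` whose
conductance is a rising sigmoid of voltage (magnesium block).

The model equations are::

    c * dv/dt = f(v) + j_kca(v, w) + j_stim(v)
    c * dw/dt = eps * g(v, w)

with ``f`` a cubic, ``j_kca`` the SK current with a fourth-power Hill
activation in ``w``, ``j_stim`` the synaptic drive, and ``g`` a piecewise
linear recovery function.  The time-calibration constant ``c`` makes ``t``
seconds, so threshold-crossing rates are in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "MinimalParams",
    "MinimalState",
    "f_cubic",
    "j_kca",
    "g_recovery",
    "nmda_conductance",
    "j_stim",
    "rhs",
]


@dataclass(frozen=True)
class MinimalParams:
    """Complete parameter set of the minimal model.

    Defaults are the calibrated dimensionless set for which the unstimulated
    model pace-makes in the tonic 1–4 Hz range.  Only ``g_a`` and ``g_n``
    are intended as control parameters.
    """

    c: float = 1.1e-4  #: time calibration; t is in seconds
    eps: float = 0.01  #: slow-variable rate factor (calcium buffering)
    a1: float = -1.0  #: cubic prefactor
    a2: float = 1.35  #: cubic quadratic coefficient
    a3: float = 0.54  #: cubic linear coefficient
    a4: float = 0.0539  #: cubic constant coefficient
    g_kca: float = 0.5  #: SK maximal conductance
    e_k: float = -1.0  #: potassium reversal
    k_ca: float = 10.0  #: SK half-activation in w
    k_w: float = -0.585  #: recovery-function threshold (w-nullcline voltage)
    m_block: float = 0.2  #: magnesium-block strength of the NMDA sigmoid
    e_n: float = 0.0  #: NMDA reversal
    e_a: float = 0.0  #: AMPA reversal
    g_a: float = 0.0  #: AMPAR maximal conductance (control parameter)
    g_n: float = 0.0  #: NMDAR maximal conductance (control parameter)
    v_spike: float = -0.4  #: spike-registration threshold

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if not self.eps > 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if not self.k_ca > 0:
            raise ValueError(f"k_ca must be positive, got {self.k_ca}")
        for name in ("g_kca", "g_a", "g_n"):
            val = getattr(self, name)
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val}")
        for f_ in fields(self):
            val = getattr(self, f_.name)
            if not math.isfinite(val):
                raise ValueError(f"{f_.name} must be finite, got {val}")

    def replace(self, **changes) -> "MinimalParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Pack into the flat float array used by the compiled integrator."""
        return np.array(
            [
                self.c,
                self.eps,
                self.a1,
                self.a2,
                self.a3,
                self.a4,
                self.g_kca,
                self.e_k,
                self.k_ca,
                self.k_w,
                self.m_block,
                self.e_n,
                self.e_a,
                self.g_a,
                self.g_n,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class MinimalState:
    """State of the minimal model: membrane potential and calcium."""

    v: float
    w: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v) and math.isfinite(self.w)):
            raise ValueError(f"state must be finite, got ({self.v}, {self.w})")

    def to_array(self) -> np.ndarray:
        return np.array([self.v, self.w], dtype=np.float64)


def f_cubic(v, p: MinimalParams):
    """Cubic voltage nonlinearity ``a1*(v^3 + a2*v^2 + a3*v + a4)``.

    Stands in for the aggregate of depolarizing currents; its N-shaped
    graph above the v axis gives the v-nullcline its folds.
    """
    return p.a1 * (v ** 3 + p.a2 * v ** 2 + p.a3 * v + p.a4)


def j_kca(v, w, p: MinimalParams):
    """SK-type calcium-activated potassium current.

    ``g_kca * (e_k - v) * w^4 / (w^4 + k_ca^4)`` — outward (negative) for
    v above the potassium reversal, with fourth-power Hill activation in
    the calcium variable.
    """
    w4 = w ** 4
    return p.g_kca * (p.e_k - v) * w4 / (w4 + p.k_ca ** 4)


def g_recovery(v, w, p: MinimalParams):
    """Piecewise-linear recovery (calcium balance) function.

    For w >= 0 the calcium variable relaxes toward the vertical nullcline
    v = k_w.  For w < 0 a ``-w`` pullback with a flattened voltage slope
    restores the trajectory to the upper half-plane; this prevents the
    mirrored (w < 0) branch of the v-nullcline from creating spurious
    stable equilibria.  Exactly at w = 0 the upper branch applies.
    """
    if w >= 0:
        return v - p.k_w
    return 0.01 * (v - p.k_w) - w


def nmda_conductance(v, p: MinimalParams):
    """Voltage-dependent NMDAR conductance ``g_n / (1 + m*exp(-6 v))``.

    The sigmoid models relief of magnesium block with depolarization; it
    is strictly increasing in v, with limits 0 (hyperpolarized) and g_n
    (fully unblocked).
    """
    return p.g_n / (1.0 + p.m_block * np.exp(-6.0 * v))


def j_stim(v, p: MinimalParams):
    """Tonic synaptic drive: NMDA (voltage-gated) plus AMPA (ohmic)."""
    return nmda_conductance(v, p) * (p.e_n - v) + p.g_a * (p.e_a - v)


def rhs(state: MinimalState | np.ndarray, p: MinimalParams) -> np.ndarray:
    """Right-hand side (dv/dt, dw/dt), in 1/seconds."""
    if isinstance(state, MinimalState):
        v, w = state.v, state.w
    else:
        v, w = float(state[0]), float(state[1])
    dv = (f_cubic(v, p) + j_kca(v, w, p) + j_stim(v, p)) / p.c
    dw = p.eps * g_recovery(v, w, p) / p.c
    return np.array([dv, dw], dtype=np.float64)
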