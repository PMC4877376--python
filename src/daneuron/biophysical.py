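"""Conductance-based dopaminergic-neuron model.

Three-variable model of the subthreshold Ca2+–K+ pacemaker of a midbrain
DA neuron: membrane potential ``v`` (mV), free intracellular calcium
``Ca`` (uM), and the gating variable ``n`` of the slow ERG potassium
current.  Fast spike-producing currents are deliberately absent — spikes
are registered as upward crossings of a threshold (-40 mV) by the
underlying oscillation.

Membrane currents: an L-type calcium current with a fourth-power
activation built from alpha/beta rate functions, an SK calcium-activated
potassium current with a Hill coefficient of 4, the ERG current (n^4),
an instantaneous depolarization-limiting potassium current, a small ohmic
leak, and tonic AMPA- and NMDA-receptor conductances (the NMDA
conductance carries the voltage-dependent magnesium block).

Calcium balance is surface influx through the L-type current versus a
linear pump, scaled by the surface-to-volume ratio of a sphere of radius
``radius_um`` and the buffering coefficient ``beta_buf`` (ratio of free
to total calcium).

Units: v in mV, t in ms, Ca in uM, conductances in mS/cm^2.  Frequencies
are converted to Hz at the reporting boundary.

The numeric parameter set ships as a calibration config
(``data/biophysical_calibration.toml``); the dataclass defaults mirror it
and a unit test keeps the two in sync.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, fields, replace
from importlib import resources

import numpy as np

__all__ = [
    "BioParams",
    "BioState",
    "g_ca",
    "g_kca",
    "g_k",
    "g_nmda",
    "erg_inf",
    "erg_tau",
    "rhs",
    "load_calibration",
]

#: uA/cm^2 -> uM/ms conversion entering the calcium influx term:
#: divide the current density by z*F and convert cm/um/s/ms consistently.
_CA_CURRENT_FACTOR = 1.0e4  # um/cm * A/uA * uM/(mol/cm^3) * s/ms net factor


@dataclass(frozen=True)
class BioParams:
    """Parameter set of the biophysical model (calibration config).

    Only ``gbar_ampa`` and ``gbar_nmda`` are intended as control
    parameters; everything else is part of the calibrated cell.
    """

    c_m: float = 1.0  #: membrane capacitance, uF/cm^2
    gbar_ca: float = 0.8  #: L-type Ca maximal conductance, mS/cm^2
    e_ca: float = 100.0  #: calcium reversal, mV
    gbar_kca: float = 12.0  #: SK maximal conductance, mS/cm^2
    k_ca: float = 0.8  #: SK half-activation, uM
    gbar_erg: float = 2.0  #: ERG maximal conductance, mS/cm^2
    gbar_k: float = 4.0  #: instantaneous K conductance, mS/cm^2
    e_k: float = -90.0  #: potassium reversal, mV
    g_l: float = 0.1  #: leak conductance, mS/cm^2
    e_l: float = -45.0  #: leak reversal, mV
    gbar_ampa: float = 0.0  #: AMPAR conductance density (control), mS/cm^2
    e_ampa: float = 0.0  #: AMPA reversal, mV
    gbar_nmda: float = 0.0  #: NMDAR conductance density (control), mS/cm^2
    e_nmda: float = 0.0  #: NMDA reversal, mV
    mg: float = 2.0  #: extracellular magnesium, mM
    radius_um: float = 5.0  #: radius of the equivalent sphere, um
    beta_buf: float = 0.05  #: ratio of free to total intracellular Ca
    z_ca: float = 2.0  #: calcium valence
    faraday: float = 96485.0  #: Faraday constant, C/mol
    p_ca: float = 0.28  #: calcium pump rate, um/ms
    erg_v_half: float = -47.4  #: ERG activation half-voltage, mV
    erg_slope: float = 2.0  #: ERG activation slope, mV
    erg_tau_base: float = 62.0  #: ERG time-constant baseline, ms
    erg_tau_amp: float = 300.0  #: ERG time-constant bump amplitude, ms
    erg_tau_v1: float = -50.4  #: upper edge of the tau bump, mV
    erg_tau_v2: float = -63.4  #: lower edge of the tau bump, mV
    v_spike: float = -40.0  #: spike-registration threshold, mV
    #: 'surface_to_volume' reads the calcium prefactor as 2*beta/r;
    #: 'literal' multiplies 2*r*beta instead.
    ca_prefactor_mode: str = "surface_to_volume"

    def __post_init__(self) -> None:
        if self.ca_prefactor_mode not in ("surface_to_volume", "literal"):
            raise ValueError(
                "ca_prefactor_mode must be 'surface_to_volume' or 'literal', "
                f"got {self.ca_prefactor_mode!r}"
            )
        if not self.c_m > 0:
            raise ValueError(f"c_m must be positive, got {self.c_m}")
        if not 0 < self.beta_buf <= 1:
            raise ValueError(f"beta_buf must be in (0, 1], got {self.beta_buf}")
        if self.mg < 0:
            raise ValueError(f"mg must be non-negative, got {self.mg}")
        for name in ("gbar_ca", "gbar_kca", "gbar_erg", "gbar_k", "g_l",
                     "gbar_ampa", "gbar_nmda"):
            val = getattr(self, name)
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val}")
        for f_ in fields(self):
            val = getattr(self, f_.name)
            if isinstance(val, float) and not math.isfinite(val):
                raise ValueError(f"{f_.name} must be finite, got {val}")

    @property
    def ca_prefactor(self) -> float:
        """Composite prefactor of the calcium equation (1/um)."""
        if self.ca_prefactor_mode == "literal":
            return 2.0 * self.radius_um * self.beta_buf
        return 2.0 * self.beta_buf / self.radius_um

    def replace(self, **changes) -> "BioParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Pack into the flat float array used by the compiled integrator."""
        influx = self.ca_prefactor * _CA_CURRENT_FACTOR / (self.z_ca * self.faraday)
        pump = self.ca_prefactor * self.p_ca
        return np.array(
            [
                self.c_m,
                self.gbar_ca,
                self.e_ca,
                self.gbar_kca,
                self.k_ca,
                self.gbar_erg,
                self.gbar_k,
                self.e_k,
                self.g_l,
                self.e_l,
                self.gbar_ampa,
                self.e_ampa,
                self.gbar_nmda,
                self.e_nmda,
                self.mg,
                influx,
                pump,
                self.erg_v_half,
                self.erg_slope,
                self.erg_tau_base,
                self.erg_tau_amp,
                self.erg_tau_v1,
                self.erg_tau_v2,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class BioState:
    """State of the biophysical model: voltage, calcium, ERG gating."""

    v: float
    ca: float
    n: float

    def __post_init__(self) -> None:
        for name in ("v", "ca", "n"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.ca < 0:
            raise ValueError(f"ca must be non-negative, got {self.ca}")
        if not 0 <= self.n <= 1:
            raise ValueError(f"n must lie in [0, 1], got {self.n}")

    def to_array(self) -> np.ndarray:
        return np.array([self.v, self.ca, self.n], dtype=np.float64)


def _alpha_ca(v):
    """Opening rate of the L-type activation gate, with the removable
    singularity at v = -50 mV evaluated by its limit."""
    x = np.asarray(v, dtype=float) + 50.0
    small = np.abs(x) < 1e-9
    xs = np.where(small, 1.0, x)
    out = 0.0032 * xs / (1.0 - np.exp(-xs / 5.0))
    out = np.where(small, 0.0032 * 5.0, out)
    return out if out.ndim else float(out)


def _beta_ca(v):
    """Closing rate of the L-type activation gate."""
    return 0.05 * np.exp(-(np.asarray(v, dtype=float) + 55.0) / 40.0)


def g_ca(v, p: BioParams):
    """L-type calcium conductance ``gbar_ca * (alpha/(alpha+beta))^4``."""
    a = _alpha_ca(v)
    b = _beta_ca(v)
    return p.gbar_ca * (a / (a + b)) ** 4


def g_kca(ca, p: BioParams):
    """SK conductance with fourth-power Hill dependence on calcium."""
    c4 = np.asarray(ca, dtype=float) ** 4
    return p.gbar_kca * c4 / (c4 + p.k_ca ** 4)


def g_k(v, p: BioParams):
    """Instantaneous depolarization-limiting potassium conductance.

    Boltzmann sigmoid with half-activation -10 mV and slope 7 mV.
    """
    return p.gbar_k / (1.0 + np.exp(-(np.asarray(v, dtype=float) + 10.0) / 7.0))


def g_nmda(v, p: BioParams):
    """NMDAR conductance under instantaneous magnesium block."""
    return p.gbar_nmda / (
        1.0 + 0.1 * p.mg * np.exp(-0.062 * np.asarray(v, dtype=float))
    )


def erg_inf(v, p: BioParams):
    """Steady-state ERG activation (increases with depolarization)."""
    return 1.0 / (
        1.0 + np.exp(-(np.asarray(v, dtype=float) - p.erg_v_half) / p.erg_slope)
    )


def erg_tau(v, p: BioParams):
    """ERG activation time constant (ms): baseline plus a voltage bump."""
    v = np.asarray(v, dtype=float)
    s1 = 1.0 / (1.0 + np.exp((v - p.erg_tau_v1) / p.erg_slope))
    s2 = 1.0 / (1.0 + np.exp((v - p.erg_tau_v2) / p.erg_slope))
    return p.erg_tau_base + p.erg_tau_amp * (s1 - s2)


def rhs(state: BioState | np.ndarray, p: BioParams) -> np.ndarray:
    """Right-hand side (dv/dt, dCa/dt, dn/dt), in 1/ms."""
    if isinstance(state, BioState):
        v, ca, n = state.v, state.ca, state.n
    else:
        v, ca, n = (float(state[i]) for i in range(3))
    gca = g_ca(v, p)
    i_ca = gca * (p.e_ca - v)
    gk_total = g_kca(ca, p) + p.gbar_erg * n ** 4 + g_k(v, p)
    dv = (
        i_ca
        + gk_total * (p.e_k - v)
        + p.g_l * (p.e_l - v)
        + p.gbar_ampa * (p.e_ampa - v)
        + g_nmda(v, p) * (p.e_nmda - v)
    ) / p.c_m
    influx = p.ca_prefactor * _CA_CURRENT_FACTOR / (p.z_ca * p.faraday)
    dca = influx * i_ca - p.ca_prefactor * p.p_ca * ca
    dn = (erg_inf(v, p) - n) / erg_tau(v, p)
    return np.array([dv, dca, dn], dtype=np.float64)


def load_calibration(path=None) -> BioParams:
    """Load the calibration config (packaged default or a TOML file).

    The file must contain one key per :class:`BioParams` field under the
    ``[biophysical]`` table; unknown keys raise a validation error.
    """
    if path is None:
        source = resources.files("daneuron").joinpath(
            "data/biophysical_calibration.toml"
        )
        raw = tomllib.loads(source.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    table = raw.get("biophysical", raw)
    known = {f_.name for f_ in fields(BioParams)}
    unknown = set(table) - known
    if unknown:
        raise ValueError(
            f"unknown calibration keys: {sorted(unknown)}; expected a subset "
            f"of {sorted(known)}"
        )
    return BioParams(**table)
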