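"""Conductance sweeps and receptor-synergy summaries.

Maps steady-state firing frequency over grids of AMPA and NMDA receptor
conductances, for either model.  Every grid point is an independent
simulation from the standard initial state (steady-response protocol, no
parameter continuation), so the maps describe attractors, not transients.

The headline summary is the synergy percentage: the relative gain of the
global frequency maximum over the conductance plane compared to the best
frequency achievable with NMDA alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np

from .biophysical import BioParams
from .dynamics import (
    DEFAULT_DURATION,
    DEFAULT_TRANSIENT,
    FiringSummary,
    SolverSettings,
    firing_summary,
    simulate,
)
from .minimal import MinimalParams

__all__ = [
    "FrequencyMap",
    "SynergyReport",
    "steady_frequency",
    "frequency_curve",
    "frequency_map",
    "synergy_report",
    "ratio_line_profile",
    "conductance_fields",
]

ModelName = Literal["minimal", "biophysical"]

#: names of the (AMPA, NMDA) conductance fields of each parameter set
_FIELDS = {
    "minimal": ("g_a", "g_n"),
    "biophysical": ("gbar_ampa", "gbar_nmda"),
}


def conductance_fields(model: ModelName) -> tuple[str, str]:
    """(AMPA, NMDA) parameter-field names for a model."""
    return _FIELDS[model]


@dataclass
class FrequencyMap:
    """Steady firing frequency over the (g_AMPA, g_NMDA) plane.

    ``frequency`` is NaN exactly where ``regime != 'firing'``; axes are
    strictly increasing; ``frequency[i, j]`` corresponds to
    ``(ga_axis[i], gn_axis[j])``.
    """

    model: ModelName
    ga_axis: np.ndarray
    gn_axis: np.ndarray
    frequency: np.ndarray  #: Hz, shape (len(ga_axis), len(gn_axis))
    regime: np.ndarray  #: object array of regime labels, same shape
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.ga_axis), len(self.gn_axis))
        if self.frequency.shape != shape or self.regime.shape != shape:
            raise ValueError("matrix shapes must match the axes")
        for ax in (self.ga_axis, self.gn_axis):
            if len(ax) > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")
        firing = self.regime == "firing"
        if np.any(np.isnan(self.frequency[firing])):
            raise ValueError("firing points must carry a frequency")
        if np.any(~np.isnan(self.frequency[~firing])):
            raise ValueError("non-firing points must not carry a frequency")

    def to_frame(self):
        """Long-format DataFrame (g_ampa, g_nmda, frequency_hz, regime)."""
        import pandas as pd

        ga, gn = np.meshgrid(self.ga_axis, self.gn_axis, indexing="ij")
        return pd.DataFrame(
            {
                "g_ampa": ga.ravel(),
                "g_nmda": gn.ravel(),
                "frequency_hz": self.frequency.ravel(),
                "regime": self.regime.ravel(),
            }
        )


@dataclass
class SynergyReport:
    """Gain of receptor co-activation over NMDA-only stimulation."""

    f_nmda_only: float  #: max frequency along the g_AMPA = 0 line (Hz)
    f_joint: float  #: global maximum over the plane (Hz)
    argmax: tuple[float, float]  #: (g_AMPA, g_NMDA) of the joint maximum
    synergy_percent: float  #: 100 * (f_joint - f_nmda_only) / f_nmda_only

    def to_json(self) -> str:
        return json.dumps(
            {
                "f_nmda_only_hz": self.f_nmda_only,
                "f_joint_hz": self.f_joint,
                "argmax_g_ampa": self.argmax[0],
                "argmax_g_nmda": self.argmax[1],
                "synergy_percent": self.synergy_percent,
            },
            indent=2,
        )


def steady_frequency(
    model: ModelName,
    params,
    g_ampa: float,
    g_nmda: float,
    settings: SolverSettings = SolverSettings(),
    duration: Optional[float] = None,
    transient: Optional[float] = None,
) -> FiringSummary:
    """Steady-state firing summary at one point of the conductance plane.

    Runs a fresh simulation from the standard initial state, discards the
    transient, and classifies the remainder.
    """
    fa, fn = _FIELDS[model]
    p = params.replace(**{fa: float(g_ampa), fn: float(g_nmda)})
    traj = simulate(model, p, duration=duration, settings=settings)
    return firing_summary(traj, transient=transient)


def frequency_curve(
    model: ModelName,
    params,
    vary: Literal["nmda", "ampa"],
    grid: np.ndarray,
    fixed: float = 0.0,
    settings: SolverSettings = SolverSettings(),
    duration: Optional[float] = None,
    transient: Optional[float] = None,
) -> list[tuple[float, FiringSummary]]:
    """Frequency along a 1-D sweep of one receptor conductance.

    ``vary`` selects the swept receptor; ``fixed`` is the other one's
    conductance.  Points are independent; output order follows the grid.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    out = []
    for g in grid:
        ga, gn = (fixed, g) if vary == "nmda" else (g, fixed)
        try:
            fs = steady_frequency(
                model, params, ga, gn, settings, duration, transient
            )
        except Exception as exc:
            raise RuntimeError(
                f"sweep failed at {vary}={g:g} (fixed={fixed:g}): {exc}"
            ) from exc
        out.append((float(g), fs))
    return out


def frequency_map(
    model: ModelName,
    params,
    ga_grid: np.ndarray,
    gn_grid: np.ndarray,
    settings: SolverSettings = SolverSettings(),
    duration: Optional[float] = None,
    transient: Optional[float] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> FrequencyMap:
    """Full 2-D frequency and regime map over the conductance plane."""
    ga_grid = np.asarray(ga_grid, dtype=float)
    gn_grid = np.asarray(gn_grid, dtype=float)
    if ga_grid.size == 0 or gn_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    freq = np.full((len(ga_grid), len(gn_grid)), np.nan)
    regime = np.empty((len(ga_grid), len(gn_grid)), dtype=object)
    total = len(ga_grid) * len(gn_grid)
    k = 0
    for i, ga in enumerate(ga_grid):
        for j, gn in enumerate(gn_grid):
            fs = steady_frequency(
                model, params, ga, gn, settings, duration, transient
            )
            regime[i, j] = fs.regime
            if fs.frequency is not None:
                freq[i, j] = fs.frequency
            k += 1
            if progress is not None:
                progress(k, total)
    return FrequencyMap(
        model=model,
        ga_axis=ga_grid,
        gn_axis=gn_grid,
        frequency=freq,
        regime=regime,
        provenance={
            "model": model,
            "rtol": settings.rtol,
            "atol": settings.atol,
            "duration": duration or DEFAULT_DURATION[model],
            "transient": transient or DEFAULT_TRANSIENT[model],
        },
    )


def _golden_max(f, lo, hi, n_iter=20):
    """Golden-section maximization of a unimodal scalar function."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    xs = [(fc, c), (fd, d)]
    fbest, xbest = max(xs)
    return xbest, fbest


def synergy_report(
    fmap: FrequencyMap,
    params=None,
    refine: bool = True,
    settings: SolverSettings = SolverSettings(),
    duration: Optional[float] = None,
    transient: Optional[float] = None,
    refine_rounds: int = 2,
) -> SynergyReport:
    """Synergy summary of a frequency map.

    ``f_nmda_only`` is the frequency maximum along the g_AMPA = 0 line
    and ``f_joint`` the global maximum.  With ``refine=True`` (requires
    ``params``) both maxima are polished within their winning grid cells
    by alternating 1-D golden-section searches along each conductance
    axis, because grid resolution understates a smooth peak.
    """
    if fmap.ga_axis[0] != 0.0:
        raise ValueError("synergy needs the g_AMPA = 0 line in the map")
    if np.all(np.isnan(fmap.frequency[0])):
        raise ValueError("no firing on the g_AMPA = 0 line: synergy undefined")

    def freq_at(ga, gn):
        fs = steady_frequency(
            fmap.model, params, ga, gn, settings, duration, transient
        )
        return fs.frequency if fs.frequency is not None else 0.0

    # NMDA-only maximum
    row0 = fmap.frequency[0]
    j0 = int(np.nanargmax(row0))
    f_nmda = float(row0[j0])
    if refine:
        if params is None:
            raise ValueError("refinement requires the model parameter set")
        lo = fmap.gn_axis[max(j0 - 1, 0)]
        hi = fmap.gn_axis[min(j0 + 1, len(fmap.gn_axis) - 1)]
        if hi > lo:
            _, f_ref = _golden_max(lambda g: freq_at(0.0, g), lo, hi)
            f_nmda = max(f_nmda, f_ref)

    # joint maximum
    flat = np.nan_to_num(fmap.frequency, nan=0.0)
    i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
    f_joint = float(flat[i, j])
    ga_star, gn_star = float(fmap.ga_axis[i]), float(fmap.gn_axis[j])
    if refine:
        for _ in range(refine_rounds):
            lo = fmap.ga_axis[max(i - 1, 0)]
            hi = fmap.ga_axis[min(i + 1, len(fmap.ga_axis) - 1)]
            if hi > lo:
                ga_new, f_a = _golden_max(lambda g: freq_at(g, gn_star), lo, hi)
                if f_a > f_joint:
                    ga_star, f_joint = ga_new, f_a
            lo = fmap.gn_axis[max(j - 1, 0)]
            hi = fmap.gn_axis[min(j + 1, len(fmap.gn_axis) - 1)]
            if hi > lo:
                gn_new, f_n = _golden_max(lambda g: freq_at(ga_star, g), lo, hi)
                if f_n > f_joint:
                    gn_star, f_joint = gn_new, f_n

    f_joint = max(f_joint, f_nmda)
    return SynergyReport(
        f_nmda_only=f_nmda,
        f_joint=f_joint,
        argmax=(ga_star, gn_star),
        synergy_percent=100.0 * (f_joint - f_nmda) / f_nmda,
    )


def ratio_line_profile(
    model: ModelName,
    params,
    ratio: float,
    gn_grid: np.ndarray,
    settings: SolverSettings = SolverSettings(),
    duration: Optional[float] = None,
    transient: Optional[float] = None,
) -> list[tuple[float, FiringSummary]]:
    """Firing profile along the line g_AMPA = ratio * g_NMDA.

    Fixed AMPA/NMDA conductance ratios model the receptor-composition
    changes of synaptic plasticity; the profile shows whether a given
    ratio line passes through the high-frequency region of the plane or
    misses it.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    out = []
    for gn in np.asarray(gn_grid, dtype=float):
        fs = steady_frequency(
            model, params, ratio * gn, gn, settings, duration, transient
        )
        out.append((float(gn), fs))
    return out
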