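"""Simulation, spike detection, and firing-regime classification.

Spikes are not modelled explicitly: in both models the fast
spike-producing currents are subordinate to the subthreshold Ca2+–K+
oscillation, so a spike is registered whenever the voltage crosses the
spike threshold from below (-0.4 in the minimal model, -40 mV in the
biophysical one), and the firing rate is the steady-state rate of such
crossings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from . import _integrate
from .biophysical import BioParams, BioState, erg_inf
from .minimal import MinimalParams, MinimalState

__all__ = [
    "SolverSettings",
    "Trajectory",
    "FiringSummary",
    "IntegrationError",
    "simulate",
    "detect_crossings",
    "firing_summary",
    "default_initial_state",
]

ModelName = Literal["minimal", "biophysical"]

#: seconds per native time unit of each model
_TIME_SCALE = {"minimal": 1.0, "biophysical": 1e-3}

#: default transient discard, native units (10 s / 5 s)
DEFAULT_TRANSIENT = {"minimal": 10.0, "biophysical": 5000.0}

#: default simulated duration, native units (30 s / 15 s)
DEFAULT_DURATION = {"minimal": 30.0, "biophysical": 15000.0}

#: subthreshold-oscillation amplitude floor: 1% of the threshold-to-trough
#: excursion of the unstimulated model (~0.31 / ~31 mV)
AMPLITUDE_FLOOR = {"minimal": 3e-3, "biophysical": 0.3}


class IntegrationError(RuntimeError):
    """Raised when the integrator fails; carries the first bad time."""

    def __init__(self, message: str, t_bad: float):
        super().__init__(message)
        self.t_bad = t_bad


@dataclass(frozen=True)
class SolverSettings:
    """Tolerances and output sampling for the adaptive integrator."""

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = math.inf  #: native time units
    sample_dt: Optional[float] = None  #: native units; None -> model default

    def __post_init__(self) -> None:
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("tolerances must be positive")


#: default sampling interval, native units (0.5 ms equivalent in both)
_DEFAULT_SAMPLE_DT = {"minimal": 5e-4, "biophysical": 0.5}


@dataclass
class Trajectory:
    """Time-ordered state samples with solver provenance.

    ``times`` are in the model's native unit (seconds for the minimal
    model, milliseconds for the biophysical one); ``time_scale`` converts
    to seconds.
    """

    model: ModelName
    times: np.ndarray
    states: np.ndarray  #: shape (n_samples, n_vars)
    settings: SolverSettings
    initial_state: np.ndarray
    time_scale: float

    def __post_init__(self) -> None:
        if len(self.times) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states must be finite")

    @property
    def v(self) -> np.ndarray:
        """Voltage samples (first state variable)."""
        return self.states[:, 0]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self):
        """Export as a pandas DataFrame (time + state columns)."""
        import pandas as pd

        cols = {"minimal": ["v", "w"], "biophysical": ["v", "ca", "n"]}[self.model]
        frame = pd.DataFrame(self.states, columns=cols)
        frame.insert(0, "time", self.times)
        return frame


@dataclass
class FiringSummary:
    """Steady-state firing description over an analysis window."""

    regime: Literal["firing", "subthreshold_oscillation", "quiescent"]
    crossing_times: np.ndarray  #: native time units
    frequency: Optional[float]  #: Hz; present iff regime == 'firing'
    amplitude: float  #: peak-to-trough voltage excursion in the window
    threshold: float
    window: tuple[float, float]  #: native units

    def __post_init__(self) -> None:
        if (self.regime == "firing") != (self.frequency is not None):
            raise ValueError("frequency must be present iff regime is 'firing'")
        if self.frequency is not None and not self.frequency > 0:
            raise ValueError("frequency must be positive when present")

    def to_json(self) -> str:
        return json.dumps(
            {
                "regime": self.regime,
                "frequency_hz": self.frequency,
                "n_crossings": int(len(self.crossing_times)),
                "amplitude": self.amplitude,
                "threshold": self.threshold,
                "window": list(self.window),
            },
            indent=2,
        )


def default_initial_state(model: ModelName, params) -> np.ndarray:
    """Standard initial condition used throughout the package.

    Both models are simulated to an attractor; the suite separately checks
    insensitivity to a distant second initial state.
    """
    if model == "minimal":
        return np.array([-0.7, 0.1])
    return np.array([-60.0, 0.1 * params.k_ca, float(erg_inf(-60.0, params))])


def simulate(
    model: ModelName,
    params,
    duration: Optional[float] = None,
    init=None,
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Integrate a model and return a finely sampled trajectory.

    Parameters
    ----------
    model : 'minimal' or 'biophysical'
    params : MinimalParams or BioParams
    duration : simulated time in the model's native unit (s / ms);
        defaults to 30 s (minimal) or 15 s (biophysical).
    init : initial state (array or the model's state dataclass);
        defaults to :func:`default_initial_state`.
    settings : solver tolerances and sampling.
    """
    if model == "minimal":
        if not isinstance(params, MinimalParams):
            raise TypeError("minimal model requires MinimalParams")
        integ = _integrate.integrate_minimal
    elif model == "biophysical":
        if not isinstance(params, BioParams):
            raise TypeError("biophysical model requires BioParams")
        integ = _integrate.integrate_bio
    else:
        raise ValueError(f"unknown model {model!r}")

    if duration is None:
        duration = DEFAULT_DURATION[model]
    if duration <= 0:
        raise ValueError("duration must be positive")
    if init is None:
        y0 = default_initial_state(model, params)
    elif isinstance(init, (MinimalState, BioState)):
        y0 = init.to_array()
    else:
        y0 = np.asarray(init, dtype=float)

    dt = settings.sample_dt or _DEFAULT_SAMPLE_DT[model]
    ts, ys, ok, t_end = integ(
        params.to_array(),
        y0,
        0.0,
        float(duration),
        float(dt),
        settings.rtol,
        settings.atol,
        float(settings.max_step),
    )
    if not ok:
        raise IntegrationError(
            f"integration of the {model} model failed at t = {t_end:.6g} "
            "(non-finite state or step underflow)",
            t_end,
        )
    return Trajectory(
        model=model,
        times=ts,
        states=ys,
        settings=settings,
        initial_state=y0,
        time_scale=_TIME_SCALE[model],
    )


def detect_crossings(
    traj: Trajectory, threshold: float, direction: str = "up"
) -> np.ndarray:
    """Times where the voltage crosses ``threshold`` in ``direction``.

    Each crossing is located by linear interpolation between the two
    bracketing samples.  By construction consecutive upward crossings are
    separated by a downward one (the sampled trace must return below
    threshold before a new upward crossing is counted).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    v = traj.v
    t = traj.times
    if direction == "up":
        idx = np.nonzero((v[:-1] <= threshold) & (v[1:] > threshold))[0]
    else:
        idx = np.nonzero((v[:-1] >= threshold) & (v[1:] < threshold))[0]
    if len(idx) == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def firing_summary(
    traj: Trajectory,
    threshold: Optional[float] = None,
    transient: Optional[float] = None,
    min_crossings: int = 3,
    amplitude_floor: Optional[float] = None,
) -> FiringSummary:
    """Classify the steady-state regime and measure the firing rate.

    The first ``transient`` time units are discarded.  With at least
    ``min_crossings`` upward threshold crossings in the remaining window
    the regime is ``firing`` and the frequency is
    ``(count - 1) / (last - first)`` converted to Hz.  With no crossings
    the trace is a ``subthreshold_oscillation`` if its peak-to-trough
    excursion exceeds ``amplitude_floor``, else ``quiescent``.
    """
    if threshold is None:
        threshold = {"minimal": -0.4, "biophysical": -40.0}[traj.model]
    if transient is None:
        transient = DEFAULT_TRANSIENT[traj.model]
    if transient >= traj.times[-1]:
        raise ValueError(
            f"transient ({transient}) must be shorter than the trajectory "
            f"({traj.times[-1]})"
        )
    if amplitude_floor is None:
        amplitude_floor = AMPLITUDE_FLOOR[traj.model]

    mask = traj.times >= transient
    window = (float(traj.times[mask][0]), float(traj.times[-1]))
    sub = Trajectory(
        model=traj.model,
        times=traj.times[mask],
        states=traj.states[mask],
        settings=traj.settings,
        initial_state=traj.initial_state,
        time_scale=traj.time_scale,
    )
    crossings = detect_crossings(sub, threshold, "up")
    v = sub.v
    amplitude = float(v.max() - v.min())

    if len(crossings) >= min_crossings:
        span = (crossings[-1] - crossings[0]) * traj.time_scale
        freq = (len(crossings) - 1) / span
        return FiringSummary(
            regime="firing",
            crossing_times=crossings,
            frequency=float(freq),
            amplitude=amplitude,
            threshold=threshold,
            window=window,
        )
    regime = (
        "subthreshold_oscillation" if amplitude > amplitude_floor else "quiescent"
    )
    return FiringSummary(
        regime=regime,
        crossing_times=crossings,
        frequency=None,
        amplitude=amplitude,
        threshold=threshold,
        window=window,
    )
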