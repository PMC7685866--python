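"""Spectral summaries, firing-state classification, and parameter sweeps.

The cortical mean signal (PY+I1+I2)/3 of each simulation is reduced to a
dominant frequency (peak of the normalized power spectrum, DC excluded),
a peak-to-trough oscillation amplitude, and one of six firing-state labels:

    I   high saturated state   (no oscillation, elevated mean level)
    II  low saturated state    (no oscillation, low mean level — "normal")
    III spike-wave discharge   (2-4 Hz, >= 2 local maxima per cycle)
    IV  tonic                  (> 10 Hz rapid low-amplitude discharge)
    V   low-frequency clonic   (2-4 Hz slow wave, single peak per cycle)
    VI  high-frequency clonic  (5-10 Hz)

Saturated states report a dominant frequency of 0.  The SWD/clonic split in
the shared low-frequency band is morphological: a spike-and-wave cycle has
a spike peak plus a wave peak, i.e. at least two prominence-filtered local
maxima per fundamental period, whereas a clonic slow wave has one.

Sweeps run every grid point independently from the same fixed initial
condition (all-zero), which is what makes the oscillation boundaries of the
bistable regions reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace as _dc_replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.signal import argrelextrema, find_peaks

from .model import ModelParameters
from .simulate import (
    SimulationConfig,
    SimulationResult,
    cortical_mean,
    integrate,
)
from .stimulation import (
    CoordinatedReset,
    DBSTrain,
    NoStimulus,
    StepPulse,
    StimulusProtocol,
    StimulusTrace,
    current_consumption,
)

__all__ = [
    "FiringState",
    "SpectralSummary",
    "FiringStateReport",
    "BifurcationScan",
    "ParameterPlaneMap",
    "ControlEfficacy",
    "AMPLITUDE_TOL",
    "spectral_summary",
    "stable_extrema",
    "classify_state",
    "classify_simulation",
    "analysis_discard",
    "sweep_parameter",
    "sweep_plane",
    "swd_reduction",
    "default_saturation_threshold",
]

#: peak-to-trough threshold below which the cortical mean counts as steady
AMPLITUDE_TOL = 0.01

#: frequency band edges (Hz): (0, low) SWD/clonic-low, [low, high] clonic-high,
#: (high, inf) tonic
BAND_LOW = 5.0
BAND_HIGH = 10.0


class FiringState(enum.Enum):
    """The six firing regimes, numbered as conventionally labelled I-VI."""

    HIGH_SATURATED = 1
    LOW_SATURATED = 2
    SWD = 3
    TONIC = 4
    CLONIC_LOW = 5
    CLONIC_HIGH = 6

    @property
    def roman(self) -> str:
        return ["I", "II", "III", "IV", "V", "VI"][self.value - 1]

    @property
    def oscillatory(self) -> bool:
        return self.value >= 3


@dataclass(frozen=True)
class SpectralSummary:
    dominant_frequency: float
    frequencies: np.ndarray
    power: np.ndarray  # normalized so the maximum (DC excluded) is 1
    amplitude: float  # peak-to-trough of the analysis window
    mean_level: float


@dataclass(frozen=True)
class FiringStateReport:
    label: FiringState
    dominant_frequency: float
    amplitude: float
    mean_level: float


@dataclass(frozen=True)
class BifurcationScan:
    parameter: str
    values: np.ndarray
    extrema: list  # per-value array of deduplicated stable extrema
    reports: list  # per-value FiringStateReport


@dataclass(frozen=True)
class ParameterPlaneMap:
    axis1: str
    values1: np.ndarray
    axis2: str
    values2: np.ndarray
    labels: np.ndarray  # (len(values1), len(values2)) of FiringState
    frequencies: np.ndarray

    def count(self, state: FiringState) -> int:
        return int(np.sum(self.labels == state))


@dataclass(frozen=True)
class ControlEfficacy:
    n_before: int
    n_after: int
    eta: float
    current: Optional[float] = None


def _window(series, fs: float, discard: float) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    w = series[int(round(discard * fs)):]
    if len(w) < 2 * fs:
        raise ValueError("series too short after discarding the transient "
                         "(need at least 2 s)")
    return w


def spectral_summary(series, fs: float, discard: float = 5.0,
                     amplitude_tol: float = AMPLITUDE_TOL,
                     max_resolution: float = 0.05) -> SpectralSummary:
    """Dominant frequency and normalized power spectrum of a signal.

    The mean is removed before the FFT and the spectrum is zero-padded so
    the bin spacing is at most ``max_resolution`` Hz.  The dominant
    frequency is the maximum-power bin excluding DC, reported as 0 when the
    peak-to-trough amplitude is below ``amplitude_tol`` (no oscillation to
    speak of); ties break toward the lower frequency.
    """
    w = _window(series, fs, discard)
    amp = float(w.max() - w.min())
    mean = float(w.mean())
    nfft = 1 << int(np.ceil(np.log2(max(len(w), fs / max_resolution))))
    power = np.abs(np.fft.rfft(w - w.mean(), nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    pmax = power[1:].max()
    if pmax > 0:
        power = power / pmax
    dom = float(freqs[1 + int(np.argmax(power[1:]))])
    if amp < amplitude_tol:
        dom = 0.0
    return SpectralSummary(dom, freqs, power, amp, mean)


def stable_extrema(series, fs: float, discard: float = 5.0,
                   amplitude_tol: float = AMPLITUDE_TOL,
                   value_tol: float = 1e-3) -> np.ndarray:
    """Deduplicated stable local extrema of the post-transient window.

    The building block of bifurcation diagrams: an equilibrium contributes a
    single value, a simple limit cycle two, and a spike-wave cycle four or
    more.  Values closer than ``value_tol`` are merged.
    """
    w = _window(series, fs, discard)
    if w.max() - w.min() < amplitude_tol:
        return np.array([w[-1]])
    vals = np.concatenate([
        w[argrelextrema(w, np.greater)[0]],
        w[argrelextrema(w, np.less)[0]],
    ])
    if len(vals) == 0:
        return np.array([w[-1]])
    vals = np.sort(vals)
    merged = [vals[0]]
    for v in vals[1:]:
        if v - merged[-1] > value_tol:
            merged.append(v)
    return np.array(merged)


@lru_cache(maxsize=8)
def _saturation_threshold_cached(params: ModelParameters) -> float:
    from .continuation import find_equilibria

    levels = []
    for C7 in (6.0, 1.0):
        eqs = [e for e in find_equilibria(params.replace(C7=C7, C11=0.1))
               if e.stable]
        if not eqs:
            raise RuntimeError(
                f"no stable equilibrium at C7={C7} to calibrate the "
                "saturation threshold")
        levels.append(max(float(np.mean(e.state[:3])) for e in eqs))
    return 0.5 * (levels[0] + levels[1])


def default_saturation_threshold(params: Optional[ModelParameters] = None) -> float:
    """Mean-level threshold separating high from low saturated states.

    Calibrated as the midpoint of the cortical-mean equilibrium levels of
    the canonical high-saturated (C7=6) and low-saturated (C7=1) regimes at
    C11=0.1; cached per parameter set.
    """
    if params is None:
        params = ModelParameters()
    base = params.replace(C7=ModelParameters.C7, C11=ModelParameters.C11)
    return _saturation_threshold_cached(base)


def _peaks_per_period(w: np.ndarray, fs: float, freq: float, amp: float) -> float:
    """Prominence-filtered local maxima per fundamental period."""
    n_periods = int(np.floor(len(w) / fs * freq))
    if n_periods < 1:
        return 0.0
    w = w[: int(round(n_periods * fs / freq))]
    peaks, _ = find_peaks(w, prominence=0.1 * amp)
    return len(peaks) / n_periods


def classify_state(series, fs: float, discard: float = 5.0,
                   amplitude_tol: float = AMPLITUDE_TOL,
                   saturation_threshold: Optional[float] = None,
                   band_low: float = BAND_LOW,
                   band_high: float = BAND_HIGH) -> FiringStateReport:
    """Assign one of the six firing-state labels to a cortical-mean signal.

    Steady signals split into high/low saturated by mean level; oscillatory
    ones by dominant frequency (> band_high -> tonic, [band_low, band_high]
    -> high-frequency clonic) with the low band split morphologically into
    SWD (>= 2 peaks per cycle) versus low-frequency clonic.
    """
    spec = spectral_summary(series, fs, discard, amplitude_tol)
    if spec.amplitude < amplitude_tol:
        thr = (saturation_threshold if saturation_threshold is not None
               else default_saturation_threshold())
        label = (FiringState.HIGH_SATURATED if spec.mean_level > thr
                 else FiringState.LOW_SATURATED)
        return FiringStateReport(label, 0.0, spec.amplitude, spec.mean_level)
    f = spec.dominant_frequency
    if f > band_high:
        label = FiringState.TONIC
    elif f >= band_low:
        label = FiringState.CLONIC_HIGH
    else:
        w = _window(series, fs, discard)
        ppp = _peaks_per_period(w, fs, f, spec.amplitude)
        label = FiringState.SWD if ppp >= 1.5 else FiringState.CLONIC_LOW
    return FiringStateReport(label, f, spec.amplitude, spec.mean_level)


def analysis_discard(protocol: StimulusProtocol) -> float:
    """Start of the analysis window: 5 s into an unstimulated run, 5 s past
    stimulus onset otherwise (transitions settle within a few seconds)."""
    if isinstance(protocol, NoStimulus) or type(protocol) is StimulusProtocol:
        return 5.0
    return protocol.t_on + 5.0


# --------------------------------------------------------------------------
# sweeps

_PROTOCOL_AXES = {
    "A_sps": (StepPulse, "A_sps"),
    "A_dbs": (DBSTrain, "A_dbs"),
    "delta": (DBSTrain, "delta"),
    "A_re": (CoordinatedReset, "A_re"),
    "A_tc": (CoordinatedReset, "A_tc"),
}


def _apply_axis(name: str, value: float, params: ModelParameters,
                protocol: StimulusProtocol):
    """Set one swept axis: a model parameter, a stimulus amplitude, or the
    DBS pulse width."""
    if name in _PROTOCOL_AXES:
        cls, attr = _PROTOCOL_AXES[name]
        if not isinstance(protocol, cls):
            raise ValueError(
                f"axis {name!r} requires a {cls.__name__} protocol, "
                f"got {type(protocol).__name__}")
        return params, _dc_replace(protocol, **{attr: value})
    try:
        return params.replace(**{name: value}), protocol
    except TypeError:
        raise ValueError(f"unknown sweep axis {name!r}") from None


def _run_point(params, protocol, config: SimulationConfig,
               saturation_threshold):
    cfg = _dc_replace(config, params=params, protocol=protocol)
    res = integrate(cfg)
    cm = cortical_mean(res)
    discard = analysis_discard(protocol)
    report = classify_state(cm, cfg.fs, discard,
                            saturation_threshold=saturation_threshold)
    return res, cm, discard, report


def sweep_parameter(name: str, values: Sequence[float],
                    params: Optional[ModelParameters] = None,
                    protocol: Optional[StimulusProtocol] = None,
                    config: Optional[SimulationConfig] = None,
                    saturation_threshold: Optional[float] = None,
                    ) -> BifurcationScan:
    """One-parameter bifurcation scan from the fixed initial condition.

    Each value is simulated independently (no warm-starting from the
    neighbouring point): the scan shows which attractor the zero state
    reaches, which is exactly how bistable windows appear in it.
    """
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    params = params if params is not None else ModelParameters()
    protocol = protocol if protocol is not None else NoStimulus()
    config = config if config is not None else SimulationConfig()
    if saturation_threshold is None:
        saturation_threshold = default_saturation_threshold(params)
    extrema, reports = [], []
    for v in values:
        p, proto = _apply_axis(name, float(v), params, protocol)
        res, cm, discard, report = _run_point(p, proto, config,
                                              saturation_threshold)
        extrema.append(stable_extrema(cm, config.fs, discard))
        reports.append(report)
    return BifurcationScan(name, values, extrema, reports)


def sweep_plane(axis1: str, values1: Sequence[float],
                axis2: str, values2: Sequence[float],
                params: Optional[ModelParameters] = None,
                protocol: Optional[StimulusProtocol] = None,
                config: Optional[SimulationConfig] = None,
                saturation_threshold: Optional[float] = None,
                ) -> ParameterPlaneMap:
    """Two-parameter map of firing-state labels and dominant frequencies.

    Grid points are independent simulations, so the result does not depend
    on evaluation order.
    """
    values1 = np.asarray(list(values1), dtype=float)
    values2 = np.asarray(list(values2), dtype=float)
    if len(values1) == 0 or len(values2) == 0:
        raise ValueError("both grids must be non-empty")
    params = params if params is not None else ModelParameters()
    protocol = protocol if protocol is not None else NoStimulus()
    config = config if config is not None else SimulationConfig()
    if saturation_threshold is None:
        saturation_threshold = default_saturation_threshold(params)
    labels = np.empty((len(values1), len(values2)), dtype=object)
    freqs = np.zeros((len(values1), len(values2)))
    for i, v1 in enumerate(values1):
        p1, proto1 = _apply_axis(axis1, float(v1), params, protocol)
        for j, v2 in enumerate(values2):
            p, proto = _apply_axis(axis2, float(v2), p1, proto1)
            _, _, _, report = _run_point(p, proto, config,
                                         saturation_threshold)
            labels[i, j] = report.label
            freqs[i, j] = report.dominant_frequency
    return ParameterPlaneMap(axis1, values1, axis2, values2, labels, freqs)


def swd_reduction(before: ParameterPlaneMap, after: ParameterPlaneMap,
                  trace: Optional[StimulusTrace] = None) -> ControlEfficacy:
    """Fraction of the parameter plane cleared of spike-wave discharge.

    eta = (N1 - N2)/N1 with N1/N2 the SWD cell counts before/after the
    stimulation protocol; undefined (error) when the plane held no SWD to
    begin with.
    """
    if (before.labels.shape != after.labels.shape
            or not np.array_equal(before.values1, after.values1)
            or not np.array_equal(before.values2, after.values2)):
        raise ValueError("maps must share an identical grid")
    n1 = before.count(FiringState.SWD)
    n2 = after.count(FiringState.SWD)
    if n1 == 0:
        raise ValueError("no SWD cells in the reference map: "
                         "reduction is undefined")
    current = current_consumption(trace) if trace is not None else None
    return ControlEfficacy(n1, n2, (n1 - n2) / n1, current)
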