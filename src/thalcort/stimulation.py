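"""Stimulation protocols driving the thalamic populations.

Three waveform families are provided, all delivered to the reticular
nucleus (u1) and/or the relay nucleus (u2):

* a sustained step ("single-pulse") of amplitude ``A_sps`` switched on at
  ``t_on``, used to probe state transitions and as the continuation axis of
  the stimulated system;
* a deep-brain-stimulation (DBS) pulse train: a periodic rectangular wave
  built from Heaviside functions of two phase-shifted sinusoids,
  ``u(t) = A * H(sin(2*pi*t/p)) * (1 - H(sin(2*pi*(t+delta)/p)))``,
  which is high for a window of width ``delta`` once per period ``p``;
* 3:2 coordinated reset stimulation (CRS): a 100 Hz rectangular pulse
  train (pulse width 1 ms) organized in repeating blocks of five pulse
  cycles — the first three delivering pulses, the last two silent —
  applied simultaneously to RE (amplitude ``A_re``) and TC (``A_tc``).

All waveforms are exactly zero before their onset time.  The Heaviside
convention is ``H(0) = 1``; at 1 ms sampling this only affects a
measure-zero set of grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "StimulusProtocol",
    "NoStimulus",
    "StepPulse",
    "DBSTrain",
    "CoordinatedReset",
    "StimulusTrace",
    "step_pulse_waveform",
    "dbs_waveform",
    "crs_waveform",
    "current_consumption",
    "protocol_from_dict",
]


def _heaviside(x):
    """Heaviside step with H(0) = 1."""
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


def step_pulse_waveform(t, A_sps: float, t_on: float, duration: Optional[float] = None):
    """Sustained step of amplitude ``A_sps`` from ``t_on`` onward.

    With ``duration`` set, the step ends at ``t_on + duration``; the default
    sustains it to the end of the window, which is the reading under which
    the stimulated system's bifurcation structure (with A_sps as the
    continuation parameter) is meaningful.
    """
    t = np.asarray(t, dtype=float)
    on = t >= t_on
    if duration is not None:
        on = on & (t < t_on + duration)
    out = np.where(on, A_sps, 0.0)
    return float(out) if out.ndim == 0 else out


def dbs_waveform(t, A_dbs: float, p: float, delta: float, t_on: float = 0.0):
    """DBS pulse train; high for a width-``delta`` window once per period ``p``."""
    if not 0 < delta < p:
        raise ValueError("require 0 < delta < p for a non-degenerate pulse train")
    t = np.asarray(t, dtype=float)
    u = (
        A_dbs
        * _heaviside(np.sin(2 * np.pi * t / p))
        * (1.0 - _heaviside(np.sin(2 * np.pi * (t + delta) / p)))
    )
    out = np.where(t >= t_on, u, 0.0)
    return float(out) if out.ndim == 0 else out


def crs_waveform(
    t,
    A_re: float,
    A_tc: float,
    f_pulse: float = 100.0,
    w: float = 0.001,
    t_on: float = 10.0,
    n_on: int = 3,
    n_off: int = 2,
    tc_cycle_offset: int = 0,
):
    """3:2 coordinated reset pulse pattern on (RE, TC).

    Pulse cycles of length 1/f_pulse repeat in blocks of ``n_on + n_off``;
    the first ``n_on`` cycles of each block deliver one rectangular pulse of
    width ``w`` each, the rest are silent.  ``tc_cycle_offset`` shifts the
    TC channel's block pattern by whole pulse cycles so that alternative
    per-target phasings can be expressed.  Returns the (u1, u2) pair.
    """
    if f_pulse <= 0:
        raise ValueError("f_pulse must be positive")
    if not 0 < w <= 1.0 / f_pulse:
        raise ValueError("pulse width must satisfy 0 < w <= 1/f_pulse")
    t = np.asarray(t, dtype=float)
    tau = t - t_on
    cycle = np.floor(tau * f_pulse)
    in_pulse = (tau - cycle / f_pulse) < w
    block = n_on + n_off

    def channel(amp, offset):
        on_cycle = np.mod(cycle + offset, block) < n_on
        u = np.where((tau >= 0) & on_cycle & in_pulse, amp, 0.0)
        return float(u) if u.ndim == 0 else u

    return channel(A_re, 0), channel(A_tc, tc_cycle_offset)


# --------------------------------------------------------------------------
# protocol objects


@dataclass(frozen=True)
class StimulusProtocol:
    """Base class: no stimulation. Subclasses override :meth:`waveforms`."""

    kind = "none"
    t_on: float = 0.0

    def __post_init__(self):
        if self.t_on < 0:
            raise ValueError("t_on must be non-negative")

    def waveforms(self, t):
        """Evaluate (u1, u2) at times ``t`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        z = np.zeros_like(t)
        return z, z

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kind"] = self.kind
        return d


class NoStimulus(StimulusProtocol):
    pass


@dataclass(frozen=True)
class StepPulse(StimulusProtocol):
    """Sustained step on RE from ``t_on`` (optionally of finite duration)."""

    kind = "step_pulse"
    A_sps: float = 0.0
    t_on: float = 10.0
    duration: Optional[float] = None

    def waveforms(self, t):
        t = np.asarray(t, dtype=float)
        u1 = step_pulse_waveform(t, self.A_sps, self.t_on, self.duration)
        return np.broadcast_to(np.asarray(u1), t.shape).copy(), np.zeros_like(t)


@dataclass(frozen=True)
class DBSTrain(StimulusProtocol):
    """Periodic rectangular DBS pulse train on RE."""

    kind = "dbs"
    A_dbs: float = 0.0
    p: float = 0.1
    delta: float = 0.001
    t_on: float = 10.0

    def __post_init__(self):
        super().__post_init__()
        if not 0 < self.delta < self.p:
            raise ValueError("require 0 < delta < p")

    def waveforms(self, t):
        t = np.asarray(t, dtype=float)
        u1 = dbs_waveform(t, self.A_dbs, self.p, self.delta, self.t_on)
        return np.broadcast_to(np.asarray(u1), t.shape).copy(), np.zeros_like(t)


@dataclass(frozen=True)
class CoordinatedReset(StimulusProtocol):
    """3:2 coordinated reset pulse trains on RE and TC simultaneously."""

    kind = "crs"
    A_re: float = 0.0
    A_tc: float = 0.0
    f_pulse: float = 100.0
    w: float = 0.001
    t_on: float = 10.0
    n_on: int = 3
    n_off: int = 2
    tc_cycle_offset: int = 0

    def __post_init__(self):
        super().__post_init__()
        if self.f_pulse <= 0 or not 0 < self.w <= 1.0 / self.f_pulse:
            raise ValueError("require f_pulse > 0 and 0 < w <= 1/f_pulse")

    def waveforms(self, t):
        t = np.asarray(t, dtype=float)
        u1, u2 = crs_waveform(
            t, self.A_re, self.A_tc, self.f_pulse, self.w,
            self.t_on, self.n_on, self.n_off, self.tc_cycle_offset,
        )
        return (
            np.broadcast_to(np.asarray(u1), t.shape).copy(),
            np.broadcast_to(np.asarray(u2), t.shape).copy(),
        )


_PROTOCOL_KINDS = {
    "none": NoStimulus,
    "step_pulse": StepPulse,
    "dbs": DBSTrain,
    "crs": CoordinatedReset,
}


def protocol_from_dict(d: dict) -> StimulusProtocol:
    """Build a protocol from a flat key-value mapping with a ``kind`` key."""
    d = dict(d)
    kind = d.pop("kind", "none")
    try:
        cls = _PROTOCOL_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown protocol kind {kind!r}") from None
    return cls(**d)


# --------------------------------------------------------------------------
# traces and the energy metric


@dataclass(frozen=True)
class StimulusTrace:
    """Sampled stimulus delivered to (RE, TC) on the simulation grid."""

    times: np.ndarray
    u1: np.ndarray
    u2: np.ndarray

    def __post_init__(self):
        if not (len(self.times) == len(self.u1) == len(self.u2)):
            raise ValueError("trace arrays must have equal length")

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time": self.times, "u1": self.u1, "u2": self.u2}).to_csv(
            path, index=False
        )


def current_consumption(trace: StimulusTrace) -> float:
    """Mean current-consumption index of a delivered stimulus.

    The Euclidean norm of the stacked (u1, u2) samples divided by the
    number of time steps; zero iff no stimulus was delivered.
    """
    if trace.n_steps == 0:
        raise ValueError("empty stimulus trace")
    stacked = np.concatenate([np.asarray(trace.u1), np.asarray(trace.u2)])
    return float(np.linalg.norm(stacked) / trace.n_steps)
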