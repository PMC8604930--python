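"""Uniformly sampled stimulus/response sweeps and step-protocol definitions.

These containers are the universal in-memory record for both voltage-clamp
(response in nA, command in mV) and current-clamp (response in mV, command in
pA) data.  Time is in ms and sampling must be uniform; the default sampling
rate is 40 kHz (dt = 0.025 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Sweep", "SweepSet", "StepProtocol", "DT_40KHZ"]

DT_40KHZ = 0.025  # ms, 40 kHz acquisition


@dataclass
class Sweep:
    """One stimulus + response time series.

    ``t`` (ms) must be uniform; ``y`` is the response (units in ``y_units``),
    ``command`` the stimulus on the same time base.  ``meta`` carries protocol
    identity, the test level of the swept segment, etc.
    """

    t: np.ndarray
    y: np.ndarray
    command: np.ndarray
    y_units: str = "nA"
    command_units: str = "mV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        if not (len(self.t) == len(self.y) == len(self.command)):
            raise ValueError("t, y and command must have equal length")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniformly sampled")

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return float(self.t[1] - self.t[0])

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.dt

    def window(self, t0: float, t1: float) -> slice:
        """Index slice for samples with t0 <= t < t1."""
        i0 = int(np.searchsorted(self.t, t0 - 1e-9))
        i1 = int(np.searchsorted(self.t, t1 - 1e-9))
        return slice(i0, i1)


@dataclass
class SweepSet:
    """An ordered collection of sweeps sharing a protocol."""

    sweeps: list
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i):
        return self.sweeps[i]


@dataclass(frozen=True)
class StepProtocol:
    """A voltage-step protocol: fixed segments plus one swept test segment.

    ``segments`` are (level mV, duration ms) pairs applied in order before the
    swept segment; ``test_levels`` are the voltages of the swept segment, one
    sweep per level, each lasting ``test_duration`` ms.  ``holding`` is applied
    for ``pre_duration`` ms before the first segment (and between sweeps for
    ``intersweep`` ms, which only matters for stateful channel models).
    """

    holding: float
    segments: tuple
    test_levels: tuple
    test_duration: float
    pre_duration: float = 5.0
    intersweep: float = 2000.0
    dt: float = DT_40KHZ

    def __post_init__(self) -> None:
        if len(self.test_levels) == 0:
            raise ValueError("test_levels must be nonempty")
        if any(d <= 0 for _, d in self.segments) or self.test_duration <= 0:
            raise ValueError("segment durations must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def command_for(self, test_level: float) -> np.ndarray:
        """Command waveform (mV) for one sweep at the given test level."""
        parts = [(self.holding, self.pre_duration)]
        parts += list(self.segments)
        parts.append((test_level, self.test_duration))
        n_total = int(round(sum(d for _, d in parts) / self.dt))
        cmd = np.empty(n_total)
        i = 0
        for level, dur in parts:
            n = int(round(dur / self.dt))
            cmd[i:i + n] = level
            i += n
        return cmd[:i] if i < n_total else cmd

    def time_axis(self, test_level: float | None = None) -> np.ndarray:
        n = len(self.command_for(self.test_levels[0]))
        return np.arange(n) * self.dt

    @property
    def test_onset(self) -> float:
        """Time (ms) at which the swept test segment begins."""
        return self.pre_duration + sum(d for _, d in self.segments)


def resurgent_protocol(test_levels=(15.0, 0.0, -15.0, -30.0, -45.0, -60.0, -75.0),
                       holding: float = -90.0,
                       conditioning: float = 30.0,
                       conditioning_duration: float = 10.0,
                       test_duration: float = 100.0,
                       dt: float = DT_40KHZ) -> StepProtocol:
    """The standard resurgent-current protocol.

    Hold at -90 mV, condition at +30 mV for 10 ms to open (and block) the
    Na+ channels, then step to each test level for ``test_duration`` ms to
    elicit the resurgent current.  Default test levels run +15..-75 mV in
    -15 mV decrements.
    """
    return StepProtocol(
        holding=holding,
        segments=((conditioning, conditioning_duration),),
        test_levels=tuple(test_levels),
        test_duration=test_duration,
        dt=dt,
    )
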