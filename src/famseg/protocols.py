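"""Voltage-clamp protocol definitions.

Four stimulus presets are provided, matching standard whole-cell
characterization of a voltage-gated calcium channel:

``iv``
    20 ms steps from -60 to +70 mV in 5 mV increments, holding -80 mV.
``ssi``
    Long conditioning pulse (5 s, enough for inactivation to equilibrate)
    at each level from -100 to +30 mV in 5 mV steps, then a +20 mV test
    pulse whose peak probes channel availability.
``tail``
    +20 mV for 20 ms to open channels, then 30 ms repolarizing test pulses
    from -80 to +10 mV in 5 mV steps; tail decay gives deactivation kinetics.
``slow_inact``
    A single 3 s step from -80 to +20 mV; the post-peak decay gives the
    time constant of slow inactivation.

Each protocol is a sequence of constant-voltage segments; a segment level of
``None`` means "use the per-sweep level". Sampling intervals default to
0.05 ms for millisecond-scale protocols and 1 ms for multi-second ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Segment", "VoltageProtocol", "protocol_preset", "PROTOCOL_NAMES"]

PROTOCOL_NAMES = ("iv", "ssi", "tail", "slow_inact")


@dataclass(frozen=True)
class Segment:
    duration_ms: float
    level_mV: Optional[float]  # None -> substitute the sweep level

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class VoltageProtocol:
    name: str
    holding_mV: float
    segments: tuple[Segment, ...]
    sweep_levels: tuple[float, ...]
    sample_interval_ms: float
    test_segment: int  # index of the segment analysed for peak current
    peak_window_ms: Optional[float] = None  # cap on peak search within test segment

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if not self.sweep_levels:
            raise ValueError("protocol needs at least one sweep level")
        if not 0 <= self.test_segment < len(self.segments):
            raise ValueError("test_segment out of range")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample interval must be positive")

    @property
    def total_duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_ms / self.sample_interval_ms))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_ms

    def segment_bounds(self) -> list[tuple[float, float]]:
        """(start, end) in ms for each segment."""
        bounds = []
        t0 = 0.0
        for seg in self.segments:
            bounds.append((t0, t0 + seg.duration_ms))
            t0 += seg.duration_ms
        return bounds

    def segment_levels(self, sweep_level: float) -> list[float]:
        return [
            sweep_level if s.level_mV is None else s.level_mV for s in self.segments
        ]

    def voltage_trace(self, sweep_level: float) -> np.ndarray:
        """Command voltage at every sample time for one sweep."""
        v = np.empty(self.n_samples)
        t = self.times()
        levels = self.segment_levels(sweep_level)
        for (t0, t1), lv in zip(self.segment_bounds(), levels):
            v[(t >= t0) & (t < t1)] = lv
        return v

    def test_window(self) -> tuple[float, float]:
        """Time window (ms) searched for the peak current."""
        t0, t1 = self.segment_bounds()[self.test_segment]
        if self.peak_window_ms is not None:
            t1 = min(t1, t0 + self.peak_window_ms)
        return t0, t1


def _levels(start: float, stop: float, step: float = 5.0) -> tuple[float, ...]:
    return tuple(np.arange(start, stop + step / 2, step, dtype=float))


def protocol_preset(name: str) -> VoltageProtocol:
    """Return one of the four named stimulus presets."""
    if name == "iv":
        return VoltageProtocol(
            name="iv",
            holding_mV=-80.0,
            segments=(
                Segment(5.0, -80.0),
                Segment(20.0, None),
                Segment(5.0, -80.0),
            ),
            sweep_levels=_levels(-60, 70),
            sample_interval_ms=0.05,
            test_segment=1,
        )
    if name == "ssi":
        return VoltageProtocol(
            name="ssi",
            holding_mV=-80.0,
            segments=(
                Segment(5000.0, None),  # conditioning, >= 10 tau_inact
                Segment(20.0, 20.0),  # availability test pulse
            ),
            sweep_levels=_levels(-100, 30),
            sample_interval_ms=1.0,
            test_segment=1,
        )
    if name == "tail":
        return VoltageProtocol(
            name="tail",
            holding_mV=-80.0,
            segments=(
                Segment(20.0, 20.0),  # activating prepulse
                Segment(30.0, None),  # repolarizing test pulse
            ),
            sweep_levels=_levels(-80, 10),
            sample_interval_ms=0.05,
            test_segment=1,
        )
    if name == "slow_inact":
        return VoltageProtocol(
            name="slow_inact",
            holding_mV=-80.0,
            segments=(
                Segment(10.0, -80.0),
                Segment(3000.0, None),
            ),
            sweep_levels=(20.0,),
            sample_interval_ms=1.0,
            test_segment=1,
            peak_window_ms=50.0,
        )
    raise ValueError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
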