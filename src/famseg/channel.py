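"""Two-gate Hodgkin–Huxley-style model of a voltage-gated calcium channel.

The whole-cell current is

    I(t) = gmax_density * C_m * m(t) * h(t) * (V(t) - Vrev)

with a single activation gate ``m`` and a single inactivation gate ``h``.
Both gates relax first-order toward voltage-dependent Boltzmann steady
states; within a constant-voltage segment the relaxation is a linear ODE, so
the simulator uses the exact exponential solution rather than a stepped
integrator. The driving force is ohmic — the downstream analysis estimates
the reversal potential by a linear regression, which assumes exactly that.

Units: conductance density nS/pF, capacitance pF, voltage mV, time ms,
current pA (nS * mV = pA).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np

from .protocols import VoltageProtocol, protocol_preset

__all__ = [
    "ChannelParams",
    "gate_steady_state",
    "simulate_sweep",
    "channel_preset",
    "calibrate_gmax",
    "PRESET_NAMES",
]


def gate_steady_state(v, v50: float, k: float, direction: str):
    """Boltzmann steady state of a gate.

    activation:   1 / (1 + exp((v50 - v) / k))   (increases with v)
    inactivation: 1 / (1 + exp((v - v50) / k))   (decreases with v)

    ``k`` must be positive; the value is exactly 0.5 at ``v == v50``.
    """
    if k <= 0:
        raise ValueError(f"slope factor k must be positive, got {k}")
    v = np.asarray(v, dtype=float)
    if direction == "activation":
        z = (v50 - v) / k
    elif direction == "inactivation":
        z = (v - v50) / k
    else:
        raise ValueError("direction must be 'activation' or 'inactivation'")
    out = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChannelParams:
    """Ground-truth gating parameters of one channel variant.

    ``tau_act`` governs the activation gate when stepping above
    ``deact_threshold_mV``; ``tau_deact`` applies below it. The inactivation
    gate uses ``tau_inact`` for both entry and recovery (a single-tau
    simplification adequate for the protocols analysed here).
    """

    gmax_density: float  # nS/pF
    vrev: float  # mV
    v50_act: float  # mV
    k_act: float  # mV
    v50_inact: float  # mV
    k_inact: float  # mV
    tau_act: float  # ms
    tau_deact: float  # ms
    tau_inact: float  # ms
    deact_threshold_mV: float = -40.0

    def __post_init__(self) -> None:
        if self.gmax_density <= 0:
            raise ValueError("gmax_density must be positive")
        if self.k_act <= 0 or self.k_inact <= 0:
            raise ValueError("slope factors must be positive")
        if min(self.tau_act, self.tau_deact, self.tau_inact) <= 0:
            raise ValueError("time constants must be positive")

    def m_inf(self, v):
        return gate_steady_state(v, self.v50_act, self.k_act, "activation")

    def h_inf(self, v):
        return gate_steady_state(v, self.v50_inact, self.k_inact, "inactivation")

    def tau_m(self, v: float) -> float:
        return self.tau_act if v > self.deact_threshold_mV else self.tau_deact

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelParams":
        return cls(**d)


def simulate_sweep(
    params: ChannelParams,
    protocol: VoltageProtocol,
    sweep_level: float,
    noise_sd: float = 0.0,
    capacitance_pF: float = 15.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one sweep; returns (time_ms, current_pA).

    Gates start at their holding-potential steady states and are propagated
    with the exact exponential update per constant-voltage segment. Gaussian
    noise of ``noise_sd`` pA is added per sample when requested.
    """
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    t = protocol.times()
    i = np.empty_like(t)
    m = params.m_inf(protocol.holding_mV)
    h = params.h_inf(protocol.holding_mV)
    g = params.gmax_density * capacitance_pF  # nS
    levels = protocol.segment_levels(sweep_level)
    for (t0, t1), v in zip(protocol.segment_bounds(), levels):
        mask = (t >= t0) & (t < t1)
        tl = t[mask] - t0
        m_inf, h_inf = params.m_inf(v), params.h_inf(v)
        tau_m = params.tau_m(v)
        m_t = m_inf + (m - m_inf) * np.exp(-tl / tau_m)
        h_t = h_inf + (h - h_inf) * np.exp(-tl / params.tau_inact)
        i[mask] = g * m_t * h_t * (v - params.vrev)
        dur = t1 - t0
        m = m_inf + (m - m_inf) * np.exp(-dur / tau_m)
        h = h_inf + (h - h_inf) * np.exp(-dur / params.tau_inact)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=i.shape)
    return t, i


def calibrate_gmax(template: ChannelParams, target_peak_density: float) -> float:
    """Conductance density giving a target noiseless peak current density.

    Runs the current–voltage protocol at unit conductance density and scales
    so the minimum (most-inward) peak density over sweeps equals the target.
    The peak density is linear in ``gmax_density``, so the scaling is exact.
    """
    if target_peak_density >= 0:
        raise ValueError("target peak density must be inward (negative)")
    proto = protocol_preset("iv")
    unit = ChannelParams(**{**template.to_dict(), "gmax_density": 1.0})
    t0, t1 = proto.test_window()
    t = proto.times()
    win = (t >= t0) & (t < t1)
    peaks = []
    for lv in proto.sweep_levels:
        _, i = simulate_sweep(unit, proto, lv, capacitance_pF=1.0)
        seg = i[win]
        peaks.append(seg[np.argmax(np.abs(seg))])
    unit_peak = min(peaks)  # pA per (pF * nS/pF)
    return target_peak_density / unit_peak


PRESET_NAMES = ("wt", "v1686m")

# Gating parameters per variant; peak current densities are the published
# group means the conductance is calibrated to. Activation/deactivation
# kinetics are model choices (no printed values exist for them).
_PRESET_SPECS = {
    "wt": dict(
        v50_act=-1.0,
        v50_inact=-39.0,
        tau_inact=386.0,
        peak_density=-21.8,
    ),
    "v1686m": dict(
        v50_act=2.4,
        v50_inact=-35.7,
        tau_inact=316.0,
        peak_density=-21.2,
    ),
}
_SHARED = dict(vrev=40.0, k_act=3.0, k_inact=5.0, tau_act=1.5, tau_deact=1.0)


@lru_cache(maxsize=None)
def channel_preset(name: str) -> ChannelParams:
    """Named channel-variant presets: ``wt`` and ``v1686m``.

    V50s and inactivation time constants equal the published group means for
    CaV2.1 wild type and V1686M; gmax is calibrated at build time so the
    noiseless peak current density matches the published mean.
    """
    key = name.lower()
    if key not in _PRESET_SPECS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    spec = _PRESET_SPECS[key]
    template = ChannelParams(
        gmax_density=1.0,
        v50_act=spec["v50_act"],
        v50_inact=spec["v50_inact"],
        tau_inact=spec["tau_inact"],
        **_SHARED,
    )
    gmax = calibrate_gmax(template, spec["peak_density"])
    return ChannelParams(**{**template.to_dict(), "gmax_density": gmax})
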