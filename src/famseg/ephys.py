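"""Patch-clamp analysis: IV curves, reversal potential, Boltzmann and
exponential fits.

The analysis chain mirrors the standard whole-cell workflow for a
voltage-gated calcium channel:

* peak current per sweep, normalized to capacitance -> IV curve (pA/pF);
* reversal potential from an ordinary-least-squares line through the IV
  points between +10 and +30 mV (x-intercept);
* conductance transform G = I / (Vm - Vrev), normalized to max, fitted with
  a two-parameter Boltzmann for the activation V50;
* steady-state inactivation from test-pulse peaks after long conditioning,
  normalized to the maximum, fitted with the inactivation Boltzmann;
* single-exponential fits for activation, deactivation (tail) and slow
  inactivation time constants.

All fits are deterministic: fixed initialization, bounded parameters, no
randomness. Non-convergence is reported through a ``converged`` flag, never
an exception, so cohort drivers can skip cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .channel import gate_steady_state
from .cohort import SweepSet

__all__ = [
    "IVCurve",
    "BoltzmannFit",
    "ExpFit",
    "peak_current",
    "build_iv",
    "estimate_vrev",
    "activation_curve",
    "fit_boltzmann",
    "ssi_curve",
    "fit_single_exponential",
    "analyze_cell",
    "fit_table",
]


@dataclass(frozen=True)
class IVCurve:
    """Peak current density per test potential for one cell."""

    v: np.ndarray  # mV, strictly increasing
    current_density: np.ndarray  # pA/pF
    cell_id: str = ""

    def __post_init__(self) -> None:
        if len(self.v) != len(self.current_density):
            raise ValueError("v and current_density must align")
        if np.any(np.diff(self.v) <= 0):
            raise ValueError("voltage levels must be strictly increasing")


@dataclass(frozen=True)
class BoltzmannFit:
    v50: float
    k: float
    residual_norm: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class ExpFit:
    tau: float  # ms
    amplitude: float
    offset: float
    residual_norm: float
    converged: bool


# -- primitives ------------------------------------------------------------

def peak_current(
    time_ms: np.ndarray,
    current_pA: np.ndarray,
    window: tuple[float, float],
    smooth_samples: int = 5,
) -> float:
    """Signed extremum of largest magnitude within a time window (inward
    currents are negative).

    A short centered boxcar (``smooth_samples``) is applied before the
    extremum search, standing in for the low-pass filtering applied to raw
    recordings before placing a peak cursor; without it the extremum of a
    noisy trace is biased away from zero by the largest noise excursion.
    """
    t0, t1 = window
    mask = (time_ms >= t0) & (time_ms < t1)
    if not mask.any():
        raise ValueError(f"empty peak window [{t0}, {t1}) ms")
    seg = current_pA[mask]
    w = max(1, min(smooth_samples, len(seg)))
    if w > 1:
        kernel = np.ones(w) / w
        # same-length smoothing with edge correction
        seg = np.convolve(seg, kernel, mode="same") / np.convolve(
            np.ones_like(seg), kernel, mode="same"
        )
    return float(seg[np.argmax(np.abs(seg))])


def build_iv(ss: SweepSet) -> IVCurve:
    """Peak current density (pA/pF) at each sweep level of an IV recording."""
    window = ss.protocol.test_window()
    missing = [lv for lv in ss.protocol.sweep_levels if float(lv) not in ss.sweeps]
    if missing:
        raise ValueError(f"cell {ss.cell_id}: missing sweep level(s) {missing}")
    levels = np.array(sorted(ss.sweeps))
    dens = np.array(
        [peak_current(ss.time_ms, ss.sweeps[lv], window) / ss.capacitance_pF
         for lv in levels]
    )
    return IVCurve(v=levels, current_density=dens, cell_id=ss.cell_id)


def estimate_vrev(
    iv: IVCurve,
    window_mV: tuple[float, float] = (10.0, 30.0),
    min_points: int = 3,
    min_slope: float = 1e-6,
) -> float:
    """Reversal potential: x-intercept of the OLS line through the IV points
    inside ``window_mV`` (default +10..+30 mV)."""
    lo, hi = window_mV
    mask = (iv.v >= lo) & (iv.v <= hi)
    if mask.sum() < min_points:
        raise ValueError(
            f"need >= {min_points} IV points in [{lo}, {hi}] mV, have {int(mask.sum())}"
        )
    res = stats.linregress(iv.v[mask], iv.current_density[mask])
    if res.slope < min_slope:
        raise ValueError("no crossing in window: IV slope not positive")
    return float(-res.intercept / res.slope)


def activation_curve(
    iv: IVCurve,
    vrev: float,
    exclusion_mV: float = 5.0,
) -> pd.DataFrame:
    """Normalized conductance G(v)/max G with G = I/(v - vrev).

    Points within ``exclusion_mV`` of the reversal potential (and above it)
    are dropped to avoid 0/0 amplification near zero driving force.
    """
    mask = iv.v <= vrev - exclusion_mV
    v = iv.v[mask]
    g = iv.current_density[mask] / (v - vrev)
    gmax = g.max() if len(g) else 0.0
    if gmax <= 0:
        raise ValueError("no inward conductance below the reversal potential")
    return pd.DataFrame({"v": v, "g_norm": g / gmax})


def _boltzmann(v, v50, k, direction):
    return gate_steady_state(np.asarray(v, dtype=float), v50, k, direction)


def fit_boltzmann(
    v: Sequence[float],
    y: Sequence[float],
    direction: str,
    k_init: float = 5.0,
    k_max: float = 30.0,
) -> BoltzmannFit:
    """Deterministic nonlinear least-squares fit of a two-parameter Boltzmann.

    Initialization: v50 at the half-maximum crossing by linear interpolation,
    slope at ``k_init``; k is bounded in (0, ``k_max``]. Requires >= 5 points;
    a flat input (no transition sampled) returns ``converged=False``.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    span = y.max() - y.min()
    if span < 1e-3 or not np.isfinite(span):
        return BoltzmannFit(np.nan, np.nan, np.nan, len(v), False)
    # half-max crossing by interpolation for the v50 start value
    order = np.argsort(v)
    vs, ys = v[order], y[order]
    half = (ys.max() + ys.min()) / 2.0
    sign = 1.0 if direction == "activation" else -1.0
    crossings = np.nonzero(np.diff(np.sign(sign * (ys - half))) != 0)[0]
    if crossings.size:
        i = crossings[0]
        frac = (half - ys[i]) / (ys[i + 1] - ys[i])
        v50_init = vs[i] + frac * (vs[i + 1] - vs[i])
    else:
        v50_init = float(vs[np.argmin(np.abs(ys - half))])
    try:
        popt, _ = optimize.curve_fit(
            lambda vv, v50, k: _boltzmann(vv, v50, k, direction),
            v, y,
            p0=(v50_init, k_init),
            bounds=((-200.0, 1e-6), (200.0, k_max)),
            maxfev=200 * 3,
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
    except (RuntimeError, ValueError):
        return BoltzmannFit(np.nan, np.nan, np.nan, len(v), False)
    v50, k = float(popt[0]), float(popt[1])
    # reject unusable solutions: parameters pegged at a bound, or a midpoint
    # outside the sampled voltage range (the transition was not captured)
    unusable = (
        k < 1e-3
        or k > k_max - 1e-6
        or not (v.min() <= v50 <= v.max())
    )
    if unusable:
        return BoltzmannFit(v50, k, np.nan, len(v), False)
    resid = y - _boltzmann(v, v50, k, direction)
    return BoltzmannFit(v50, k, float(np.linalg.norm(resid)), len(v), True)


def ssi_curve(ss: SweepSet) -> tuple[pd.DataFrame, BoltzmannFit]:
    """Steady-state inactivation: availability per conditioning voltage plus
    its inactivation-direction Boltzmann fit.

    Availability is the test-pulse peak normalized to the largest-magnitude
    peak over conditioning levels (fully available at hyperpolarized
    conditioning by construction).
    """
    if ss.protocol.name != "ssi":
        raise ValueError(f"expected ssi protocol, got {ss.protocol.name!r}")
    window = ss.protocol.test_window()
    levels = np.array(sorted(ss.sweeps))
    peaks = np.array(
        [peak_current(ss.time_ms, ss.sweeps[lv], window) for lv in levels]
    )
    ref = peaks[np.argmax(np.abs(peaks))]
    if ref == 0:
        raise ValueError("all test-pulse peaks are zero")
    avail = peaks / ref
    fit = fit_boltzmann(levels, avail, "inactivation")
    return pd.DataFrame({"v": levels, "availability": avail}), fit


def fit_single_exponential(
    time_ms: np.ndarray,
    y: np.ndarray,
    min_samples: int = 5,
) -> ExpFit:
    """Least-squares fit of y(t) = A exp(-t/tau) + C on a trace segment.

    Time is re-zeroed to the segment start. Initialization from endpoint
    amplitudes and a tau of one fifth of the segment; a flat segment returns
    ``converged=False``.
    """
    t = np.asarray(time_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < min_samples:
        raise ValueError(f"segment has {len(t)} samples; need >= {min_samples}")
    t = t - t[0]
    span = np.ptp(y)
    scale = max(np.max(np.abs(y)), 1.0)
    if span < 1e-9 * scale:
        return ExpFit(np.nan, np.nan, float(y.mean()), 0.0, False)
    a0 = y[0] - y[-1]
    tau0 = max(t[-1] / 5.0, t[1] - t[0])
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t, y,
            p0=(a0, tau0, y[-1]),
            bounds=((-np.inf, 1e-9, -np.inf), (np.inf, np.inf, np.inf)),
            maxfev=2000,
            xtol=1e-12, ftol=1e-12,
        )
    except (RuntimeError, ValueError):
        return ExpFit(np.nan, np.nan, np.nan, np.nan, False)
    a, tau, c = map(float, popt)
    resid = y - (a * np.exp(-t / tau) + c)
    return ExpFit(tau, a, c, float(np.linalg.norm(resid)), True)


# -- phase segment selection ----------------------------------------------

def _segment_slice(ss: SweepSet, t0: float, t1: float) -> np.ndarray:
    return (ss.time_ms >= t0) & (ss.time_ms < t1)


def inactivation_tau(ss: SweepSet, level: float | None = None) -> ExpFit:
    """Tau of slow inactivation: exponential fit from the post-peak decay to
    the end of the long depolarizing step."""
    lv = level if level is not None else ss.levels[-1]
    t0, t1 = ss.protocol.segment_bounds()[ss.protocol.test_segment]
    trace = ss.sweep(lv)
    win0, win1 = ss.protocol.test_window()
    mask = _segment_slice(ss, win0, win1)
    seg = trace[mask]
    peak_idx = np.flatnonzero(mask)[np.argmax(np.abs(seg))]
    tail = slice(peak_idx, np.searchsorted(ss.time_ms, t1))
    return fit_single_exponential(ss.time_ms[tail], trace[tail])


def activation_tau(ss: SweepSet, level: float, skip_samples: int = 0) -> ExpFit:
    """Tau of activation: exponential fit from step onset to the peak."""
    t0, t1 = ss.protocol.segment_bounds()[ss.protocol.test_segment]
    mask = _segment_slice(ss, t0, t1)
    idx = np.flatnonzero(mask)[skip_samples:]
    trace = ss.sweep(level)
    peak_rel = np.argmax(np.abs(trace[idx]))
    seg = idx[: peak_rel + 1]
    if len(seg) < 5:
        seg = idx[:5]
    return fit_single_exponential(ss.time_ms[seg], trace[seg])


def deactivation_tau(ss: SweepSet, level: float, skip_samples: int = 2) -> ExpFit:
    """Tau of deactivation from a tail current, skipping the first samples
    after the repolarizing transition (capacitive-transient guard)."""
    t0, t1 = ss.protocol.segment_bounds()[ss.protocol.test_segment]
    mask = _segment_slice(ss, t0, t1)
    idx = np.flatnonzero(mask)[skip_samples:]
    return fit_single_exponential(ss.time_ms[idx], ss.sweep(level)[idx])


# -- per-cell driver -------------------------------------------------------

def analyze_cell(ss: SweepSet) -> dict:
    """Protocol-appropriate analysis of one cell; returns a flat record.

    IV protocol: peak density, reversal potential, activation V50/k and
    activation tau at +20 mV. SSI protocol: inactivation V50/k. Slow
    inactivation: tau. Tail: deactivation tau at -80 mV.
    """
    rec: dict = {
        "cell_id": ss.cell_id,
        "group": ss.group,
        "protocol": ss.protocol.name,
        "capacitance_pF": ss.capacitance_pF,
        "peak_density": np.nan,
        "vrev": np.nan,
        "v50_act": np.nan,
        "k_act": np.nan,
        "v50_inact": np.nan,
        "k_inact": np.nan,
        "tau_act": np.nan,
        "tau_deact": np.nan,
        "tau_inact": np.nan,
        "converged": True,
    }
    name = ss.protocol.name
    if name == "iv":
        iv = build_iv(ss)
        rec["peak_density"] = float(iv.current_density.min())
        try:
            vrev = estimate_vrev(iv)
        except ValueError:
            rec["converged"] = False
            return rec
        rec["vrev"] = vrev
        try:
            act = activation_curve(iv, vrev)
        except ValueError:
            rec["converged"] = False
            return rec
        fit = fit_boltzmann(act["v"], act["g_norm"], "activation")
        rec["converged"] = fit.converged
        if fit.converged:
            rec["v50_act"], rec["k_act"] = fit.v50, fit.k
        tau = activation_tau(ss, 20.0)
        rec["tau_act"] = tau.tau if tau.converged else np.nan
    elif name == "ssi":
        _, fit = ssi_curve(ss)
        rec["converged"] = fit.converged
        if fit.converged:
            rec["v50_inact"], rec["k_inact"] = fit.v50, fit.k
    elif name == "slow_inact":
        fit = inactivation_tau(ss)
        rec["converged"] = fit.converged
        if fit.converged:
            rec["tau_inact"] = fit.tau
    elif name == "tail":
        fit = deactivation_tau(ss, -80.0)
        rec["tau_deact"] = fit.tau
        rec["converged"] = fit.converged
    else:
        raise ValueError(f"no analysis defined for protocol {name!r}")
    return rec


def fit_table(cells: Sequence[SweepSet]) -> pd.DataFrame:
    """Per-cell fit table for a list of sweep sets."""
    return pd.DataFrame([analyze_cell(ss) for ss in cells])
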