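"""Simulated patch-clamp cohorts: cell-to-cell variability and disk format.

A cohort is a set of cells sharing a channel-variant preset and a stimulus
protocol. Per cell the generator draws

* conductance density: lognormal, mean preserved, given CV;
* activation / inactivation V50: normal with a common SD (mV);
* inactivation time constant: lognormal, mean preserved, given CV;
* membrane capacitance: lognormal around 15 pF;

then simulates every sweep with additive Gaussian recording noise. The
default dispersions are calibrated so that simulated group SEMs at the
published per-group cell counts match the published +/- values.

On disk each cell is one tab-separated sweep table (column 1 ``time_ms``,
one column per sweep level) plus a JSON sidecar with cell metadata and, for
simulated cells, the generating ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .channel import ChannelParams, channel_preset, simulate_sweep
from .protocols import VoltageProtocol, protocol_preset

__all__ = ["CohortSpec", "SweepSet", "generate_cohort", "write_sweepset",
           "read_sweepset", "read_cell_dir", "write_cohort"]


@dataclass
class SweepSet:
    """One cell's sweeps for one protocol."""

    cell_id: str
    group: str  # e.g. "WT" or "V1686M"
    protocol: VoltageProtocol
    capacitance_pF: float
    time_ms: np.ndarray
    sweeps: dict[float, np.ndarray]  # sweep level -> current (pA)
    truth: Optional[ChannelParams] = None

    def __post_init__(self) -> None:
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")
        n = len(self.time_ms)
        for lv, trace in self.sweeps.items():
            if len(trace) != n:
                raise ValueError(
                    f"sweep at {lv} mV has {len(trace)} samples, expected {n}"
                )

    @property
    def levels(self) -> list[float]:
        return sorted(self.sweeps)

    def sweep(self, level: float) -> np.ndarray:
        try:
            return self.sweeps[level]
        except KeyError:
            raise KeyError(
                f"cell {self.cell_id}: no sweep at level {level} mV"
            )


@dataclass
class CohortSpec:
    """Recipe for a simulated cohort of cells."""

    n_cells: int
    params: ChannelParams
    cell_cv_gmax: float = 0.5
    cell_sd_v50: float = 3.0  # mV, applied to both activation and inactivation
    cell_cv_tau: float = 0.3
    noise_sd_pA: float = 5.0
    capacitance_mean_pF: float = 15.0
    capacitance_cv: float = 0.3
    seed: int = 0
    group: str = "WT"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("cell_cv_gmax", "cell_sd_v50", "cell_cv_tau",
                     "noise_sd_pA", "capacitance_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.capacitance_mean_pF <= 0:
            raise ValueError("capacitance mean must be positive")


def _lognormal_mean_preserving(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw with the requested arithmetic mean and CV."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _draw_cell_params(spec: CohortSpec, rng: np.random.Generator) -> tuple[ChannelParams, float]:
    p = spec.params
    gmax = _lognormal_mean_preserving(rng, p.gmax_density, spec.cell_cv_gmax)
    v50a = rng.normal(p.v50_act, spec.cell_sd_v50) if spec.cell_sd_v50 else p.v50_act
    v50i = rng.normal(p.v50_inact, spec.cell_sd_v50) if spec.cell_sd_v50 else p.v50_inact
    tau_i = _lognormal_mean_preserving(rng, p.tau_inact, spec.cell_cv_tau)
    cm = _lognormal_mean_preserving(rng, spec.capacitance_mean_pF, spec.capacitance_cv)
    truth = ChannelParams(
        **{
            **p.to_dict(),
            "gmax_density": gmax,
            "v50_act": v50a,
            "v50_inact": v50i,
            "tau_inact": tau_i,
        }
    )
    return truth, cm


def generate_cohort(spec: CohortSpec, protocol: VoltageProtocol | str) -> list[SweepSet]:
    """Simulate ``spec.n_cells`` cells under one protocol.

    Deterministic for a fixed ``spec.seed``: per-cell streams are spawned
    from a single seed sequence, so cell k's data does not depend on how
    many cells are generated.
    """
    if isinstance(protocol, str):
        protocol = protocol_preset(protocol)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_cells)
    cells = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        truth, cm = _draw_cell_params(spec, rng)
        sweeps = {}
        for lv in protocol.sweep_levels:
            _, i = simulate_sweep(
                truth, protocol, lv,
                noise_sd=spec.noise_sd_pA, capacitance_pF=cm, rng=rng,
            )
            sweeps[float(lv)] = i
        cells.append(
            SweepSet(
                cell_id=f"{spec.group}_{protocol.name}_{k:03d}",
                group=spec.group,
                protocol=protocol,
                capacitance_pF=cm,
                time_ms=protocol.times(),
                sweeps=sweeps,
                truth=truth,
            )
        )
    return cells


# -- disk format -----------------------------------------------------------

def write_sweepset(ss: SweepSet, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one cell as ``<cell_id>.tsv`` plus ``<cell_id>.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_ms": ss.time_ms})
    for lv in ss.levels:
        df[f"{lv:g}"] = ss.sweeps[lv]
    tsv = out_dir / f"{ss.cell_id}.tsv"
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    meta = {
        "cell_id": ss.cell_id,
        "group": ss.group,
        "capacitance_pF": ss.capacitance_pF,
        "protocol": ss.protocol.name,
        "truth": ss.truth.to_dict() if ss.truth is not None else None,
    }
    sidecar = out_dir / f"{ss.cell_id}.json"
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return tsv, sidecar


def read_sweepset(tsv_path: str | Path) -> SweepSet:
    """Read one cell written by :func:`write_sweepset`."""
    tsv_path = Path(tsv_path)
    sidecar = tsv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(tsv_path, sep="\t")
    protocol = protocol_preset(meta["protocol"])
    sweeps = {
        float(col): df[col].to_numpy()
        for col in df.columns
        if col != "time_ms"
    }
    truth = meta.get("truth")
    return SweepSet(
        cell_id=meta["cell_id"],
        group=meta["group"],
        protocol=protocol,
        capacitance_pF=float(meta["capacitance_pF"]),
        time_ms=df["time_ms"].to_numpy(),
        sweeps=sweeps,
        truth=ChannelParams.from_dict(truth) if truth else None,
    )


def read_cell_dir(path: str | Path) -> list[SweepSet]:
    """Read every cell (``*.tsv`` with JSON sidecar) in a directory."""
    path = Path(path)
    return [read_sweepset(p) for p in sorted(path.glob("*.tsv"))]


def write_cohort(cells: list[SweepSet], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    for ss in cells:
        write_sweepset(ss, out_dir)
    return out_dir


def cohort_for_preset(
    preset: str,
    protocol: str,
    n_cells: int,
    seed: int,
    group: str | None = None,
    **overrides,
) -> list[SweepSet]:
    """Convenience wrapper: cohort from a named channel preset."""
    spec = CohortSpec(
        n_cells=n_cells,
        params=channel_preset(preset),
        seed=seed,
        group=group or ("WT" if preset.lower() == "wt" else "V1686M"),
        **overrides,
    )
    return generate_cohort(spec, protocol)
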