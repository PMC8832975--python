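"""Group statistics for two-cohort electrophysiology comparisons.

Two modes, matching field convention:

* ``t_test`` — unpaired two-sided Student's t (pooled variance) for scalar
  quantities such as V50s, time constants and peak densities.
* ``two_way_anova_sidak`` — fixed-effects two-way ANOVA (group x voltage,
  with interaction, cells as replicates) for voltage-indexed curves,
  followed by per-voltage comparisons with a Sidak multiple-comparison
  adjustment: p_adj = 1 - (1 - p)^m for m voltage levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = ["GroupStats", "compare_groups", "sidak_adjust"]


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak-adjusted p-value for m comparisons; never below the raw p."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p)) ** m if np.ndim(p) else float(1.0 - (1.0 - p) ** m)


@dataclass(frozen=True)
class GroupSummary:
    name: str
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class GroupStats:
    comparison: str
    test: str  # "t_test" | "two_way_anova_sidak"
    groups: tuple[GroupSummary, GroupSummary]
    statistic: float
    p_value: float
    per_voltage: Optional[pd.DataFrame] = None  # voltage, p_raw, p_sidak
    anova_table: Optional[pd.DataFrame] = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _summary(name: str, x: np.ndarray) -> GroupSummary:
    n = len(x)
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return GroupSummary(name, float(np.mean(x)), sem, n)


def _t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    a,
    b,
    quantity: str,
    mode: str = "t_test",
    group_names: tuple[str, str] = ("WT", "variant"),
    voltages: Optional[Sequence[float]] = None,
) -> GroupStats:
    """Compare two cohorts on one quantity.

    ``t_test`` expects 1-D arrays of per-cell scalars. ``two_way_anova_sidak``
    expects 2-D arrays (cells x voltages) plus the voltage levels; the group
    main-effect F and p are reported, with Sidak-adjusted per-voltage t-tests
    alongside. Both groups need at least two cells.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "t_test":
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 converged cells")
        stat, p = _t_test(a, b)
        return GroupStats(
            comparison=quantity,
            test="t_test",
            groups=(_summary(group_names[0], a), _summary(group_names[1], b)),
            statistic=stat,
            p_value=p,
        )

    if mode != "two_way_anova_sidak":
        raise ValueError(f"unknown mode {mode!r}")
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("ANOVA mode expects cells x voltages matrices")
    if voltages is None or len(voltages) != a.shape[1] or a.shape[1] != b.shape[1]:
        raise ValueError("voltages must match the matrix columns")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 cells")

    volts = np.asarray(voltages, dtype=float)
    frames = []
    for g, mat in zip(group_names, (a, b)):
        n_cells = mat.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "value": mat.ravel(),
                    "group": g,
                    "voltage": np.tile(volts, n_cells),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True).dropna()
    model = ols("value ~ C(group) * C(voltage)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_group = float(table.loc["C(group)", "F"])
    p_group = float(table.loc["C(group)", "PR(>F)"])

    m = len(volts)
    rows = []
    for j, v in enumerate(volts):
        col_a = a[:, j][np.isfinite(a[:, j])]
        col_b = b[:, j][np.isfinite(b[:, j])]
        if len(col_a) > 1 and len(col_b) > 1:
            _, p_raw = _t_test(col_a, col_b)
        else:
            p_raw = np.nan
        rows.append({"voltage": v, "p_raw": p_raw, "p_sidak": sidak_adjust(p_raw, m)})
    per_voltage = pd.DataFrame(rows)

    return GroupStats(
        comparison=quantity,
        test="two_way_anova_sidak",
        groups=(
            _summary(group_names[0], a[np.isfinite(a)]),
            _summary(group_names[1], b[np.isfinite(b)]),
        ),
        statistic=f_group,
        p_value=p_group,
        per_voltage=per_voltage,
        anova_table=table,
    )
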