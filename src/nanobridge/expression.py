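"""Relative expression quantification: ΔΔCt fold changes and marker summaries.

Implements the standard comparative-Ct method for qPCR with a reference
small RNA (RNU44-style) and a calibrator condition:

    ΔCt  = mean Ct(target) − mean Ct(reference)          per condition
    ΔΔCt = ΔCt(condition) − ΔCt(calibrator)
    fold = 2^(−ΔΔCt)

Amplification efficiency is fixed at 2 per cycle (not estimated).  Replicate
Ct values are aggregated by arithmetic mean; the CI comes from pooling
replicate s.d. onto ΔΔCt under a normal approximation.  Marker-intensity
summaries across sorted populations report medians (robust to lognormal
tails) with means alongside, and delegate significance testing to
:func:`nanobridge.morphometry.compare_groups`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import InvalidInputError
from .morphometry import GroupComparison, compare_groups

__all__ = ["FoldChangeResult", "delta_delta_ct_fold_change", "marker_mfi_summary"]

CT_MIN, CT_MAX = 0.0, 45.0
Z_95 = 1.959963984540054


@dataclass(frozen=True)
class FoldChangeResult:
    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    ci_low: float | None
    ci_high: float | None
    has_ci: bool


def _validate_ct(df: pd.DataFrame) -> None:
    required = {"condition", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"Ct table missing columns {sorted(missing)}")
    bad = df[(df["ct"] <= CT_MIN) | (df["ct"] >= CT_MAX)]
    if len(bad):
        raise InvalidInputError("Ct values must lie in (0, 45) cycles")


def delta_delta_ct_fold_change(
    records: pd.DataFrame,
    calibrator_condition: str,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> dict[str, FoldChangeResult]:
    """ΔΔCt fold change per condition relative to a calibrator condition.

    ``records`` is a tidy Ct table (columns ``condition``, ``gene``, ``ct``,
    one row per replicate).  Every condition must carry both the target and
    the reference gene; the calibrator's fold change is exactly 1.  With a
    single replicate per gene a point estimate is returned with
    ``has_ci=False``.
    """
    _validate_ct(records)
    conditions = list(records["condition"].unique())
    if calibrator_condition not in conditions:
        raise InvalidInputError(f"calibrator {calibrator_condition!r} absent from table")

    def delta_ct(cond: str) -> tuple[float, float, int]:
        sub = records[records["condition"] == cond]
        t = sub.loc[sub["gene"] == target_gene, "ct"]
        r = sub.loc[sub["gene"] == reference_gene, "ct"]
        if len(t) == 0:
            raise InvalidInputError(f"condition {cond!r} missing target gene records")
        if len(r) == 0:
            raise InvalidInputError(f"condition {cond!r} missing reference gene records")
        var = 0.0
        n_min = min(len(t), len(r))
        if len(t) > 1:
            var += t.var(ddof=1) / len(t)
        if len(r) > 1:
            var += r.var(ddof=1) / len(r)
        return float(t.mean() - r.mean()), var, n_min

    dct_cal, var_cal, n_cal = delta_ct(calibrator_condition)
    out: dict[str, FoldChangeResult] = {}
    for cond in conditions:
        dct, var, n_min = delta_ct(cond)
        if cond == calibrator_condition:
            ddct, var_ddct = 0.0, var  # calibrator vs itself: no extra spread
        else:
            ddct = dct - dct_cal
            var_ddct = var + var_cal
        fold = 2.0 ** (-ddct)
        has_ci = n_min >= 2 and min(n_cal, n_min) >= 2
        if has_ci and var_ddct > 0:
            half = Z_95 * math.sqrt(var_ddct)
            ci = (2.0 ** (-(ddct + half)), 2.0 ** (-(ddct - half)))
        elif has_ci:
            ci = (fold, fold)
        else:
            ci = (None, None)
        out[cond] = FoldChangeResult(
            condition=cond,
            delta_ct=dct,
            delta_delta_ct=ddct,
            fold_change=fold,
            ci_low=ci[0],
            ci_high=ci[1],
            has_ci=has_ci,
        )
    return out


@dataclass(frozen=True)
class MarkerSummary:
    """Per-population marker intensities with pairwise comparisons."""

    medians: Mapping[str, float]
    means: Mapping[str, float]
    comparison: GroupComparison
    direction: Mapping[str, str]  # pair label -> 'higher' | 'lower' | 'equal'


def marker_mfi_summary(
    measurements: pd.DataFrame,
    marker: str | None = None,
    population_column: str = "population",
    value_column: str = "intensity",
) -> MarkerSummary:
    """Median/mean marker intensity per sorted population, with comparisons.

    Populations are e.g. recipient / non_recipient / naive / inhibitor
    endothelial pools.  Empty populations are skipped; pairwise significance
    and effect sizes come from the shared ANOVA + Bonferroni routine, and a
    direction-of-effect report states, for each pair, whether the first
    population's median is higher, lower or equal.
    """
    if marker is not None and "marker" in measurements.columns:
        measurements = measurements[measurements["marker"] == marker]
    groups = {
        str(k): sub[value_column].dropna().to_numpy()
        for k, sub in measurements.groupby(population_column, observed=True)
        if len(sub[value_column].dropna()) > 0
    }
    if len(groups) < 2:
        raise InvalidInputError("need at least 2 non-empty populations")
    medians = {k: float(pd.Series(v).median()) for k, v in groups.items()}
    means = {k: float(v.mean()) for k, v in groups.items()}
    comparison = compare_groups(groups)
    direction = {}
    for _, row in comparison.pairwise.iterrows():
        a, b = row["group_a"], row["group_b"]
        if medians[a] > medians[b]:
            d = "higher"
        elif medians[a] < medians[b]:
            d = "lower"
        else:
            d = "equal"
        direction[f"{a} vs {b}"] = d
    return MarkerSummary(
        medians=medians, means=means, comparison=comparison, direction=direction
    )
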