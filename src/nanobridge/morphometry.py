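"""Summary statistics and classification for membrane-projection tables.

Operates on tidy tables with one row per measured projection (see
:mod:`nanobridge.synthetic` for the generator and the column contract):
dimension summaries (mean ± s.e.m.), a width/aspect-ratio rule separating
nanoscale bridges from lamellipodia, per-cell connection statistics, growth
kinetics peak detection, and the one-way ANOVA + Bonferroni group comparison
used throughout the pipelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateVarianceError, InvalidInputError

__all__ = [
    "MorphometrySummary",
    "ConnectionStats",
    "PeakInterval",
    "GroupComparison",
    "summarize_dimensions",
    "classify_projection_kind",
    "connection_stats",
    "kinetics_peak",
    "compare_groups",
    "bonferroni",
]

#: Width below which a projection can be a nanoscale bridge (nm); midway
#: between the reported bridge (0.29 μm) and lamellipodium (4.99 μm) widths.
WIDTH_THRESHOLD_NM = 1_000.0
#: Minimum long/short aspect ratio for a nanoscale bridge.
ASPECT_THRESHOLD = 10.0


@dataclass(frozen=True)
class MorphometrySummary:
    n: int
    mean: float
    sd: float
    sem: float


@dataclass(frozen=True)
class ConnectionStats:
    """Per connection class: % of cells with >=1 connection, mean/sem per cell."""

    pct_cells_with_connections: Mapping[str, float]
    connections_per_cell_mean: Mapping[str, float]
    connections_per_cell_sem: Mapping[str, float]
    n_cells: int


@dataclass(frozen=True)
class PeakInterval:
    """[earliest, latest] time attaining the top of the smoothed curve."""

    start: float
    end: float
    flat: bool = False


def summarize_dimensions(
    records: pd.DataFrame,
    field: str = "short_axis_nm",
    group_by: str | None = None,
) -> dict[str, MorphometrySummary] | MorphometrySummary:
    """Mean, sample s.d. (n−1) and s.e.m. of one dimension, optionally per group.

    Empty groups are skipped with a warning.  Returns a single summary when
    ``group_by`` is None, else a dict keyed by group label.
    """
    if field not in records.columns:
        raise InvalidInputError(f"missing column {field!r}")

    def one(values: np.ndarray) -> MorphometrySummary:
        n = values.size
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        return MorphometrySummary(n=n, mean=mean, sd=sd, sem=sd / math.sqrt(n))

    if group_by is None:
        vals = records[field].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise InvalidInputError("no values to summarize")
        return one(vals)
    out: dict[str, MorphometrySummary] = {}
    for key, sub in records.groupby(group_by, observed=True):
        vals = sub[field].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {key!r} empty for {field!r}; skipped")
            continue
        out[key] = one(vals)
    return out


def classify_projection_kind(
    short_axis_nm: float,
    long_axis_nm: float,
    width_threshold_nm: float = WIDTH_THRESHOLD_NM,
    aspect_threshold: float = ASPECT_THRESHOLD,
) -> str:
    """Nanobridge vs lamellipodium by width and aspect ratio.

    ``nanobridge`` iff the short axis is below ``width_threshold_nm`` *and*
    the long/short aspect ratio is at least ``aspect_threshold``; otherwise
    ``lamellipodium``.  Missing axes yield ``"unclassifiable"``.
    """
    if short_axis_nm is None or long_axis_nm is None:
        return "unclassifiable"
    if not (np.isfinite(short_axis_nm) and np.isfinite(long_axis_nm)):
        return "unclassifiable"
    if short_axis_nm <= 0 or long_axis_nm <= 0:
        raise InvalidInputError("axes must be positive")
    is_bridge = (
        short_axis_nm < width_threshold_nm
        and long_axis_nm / short_axis_nm >= aspect_threshold
    )
    return "nanobridge" if is_bridge else "lamellipodium"


def classify_table(records: pd.DataFrame, **kwargs) -> pd.Series:
    """Vectorized :func:`classify_projection_kind` over a projection table."""
    return records.apply(
        lambda r: classify_projection_kind(r["short_axis_nm"], r["long_axis_nm"], **kwargs),
        axis=1,
    )


def connection_stats(records: pd.DataFrame, all_cell_ids=None) -> ConnectionStats:
    """Connection statistics per class from a per-connection table.

    ``records`` needs ``cell_id`` and ``connection_class`` columns (one row
    per connection).  ``all_cell_ids`` optionally lists the full cell
    population (cells with zero connections count in the denominators);
    defaults to the cells appearing in the table.
    """
    if "cell_id" not in records.columns:
        raise InvalidInputError("records must carry cell_id")
    cells = pd.Index(all_cell_ids) if all_cell_ids is not None else pd.Index(
        records["cell_id"].unique()
    )
    n_cells = len(cells)
    if n_cells == 0:
        raise InvalidInputError("no cells")
    pct: dict[str, float] = {}
    mean: dict[str, float] = {}
    sem: dict[str, float] = {}
    for cls, sub in records.groupby("connection_class", observed=True):
        counts = sub.groupby("cell_id").size().reindex(cells, fill_value=0)
        pct[cls] = 100.0 * float((counts > 0).mean())
        mean[cls] = float(counts.mean())
        sd = float(counts.std(ddof=1)) if n_cells > 1 else 0.0
        sem[cls] = sd / math.sqrt(n_cells)
    return ConnectionStats(
        pct_cells_with_connections=pct,
        connections_per_cell_mean=mean,
        connections_per_cell_sem=sem,
        n_cells=n_cells,
    )


def kinetics_peak(
    timepoints: Sequence[float],
    means: Sequence[float],
    smoothing_window: int = 3,
    top_fraction: float = 0.95,
) -> PeakInterval:
    """Peak window of a growth curve: times attaining the top of the range.

    The means are smoothed with a centred moving average of odd width
    ``smoothing_window`` (edges use the available points), then the interval
    [earliest, latest] of timepoints whose smoothed value reaches
    ``min + top_fraction·(max − min)`` is returned — a *window*, because
    saturating growth curves have plateaus, not point maxima.  The rule is
    invariant to adding a constant to all means.  An all-equal series
    returns the full range flagged ``flat``.
    """
    t = np.asarray(list(timepoints), dtype=float)
    y = np.asarray(list(means), dtype=float)
    if t.size < 3:
        raise InvalidInputError("need at least 3 timepoints")
    if t.size != y.size:
        raise InvalidInputError("timepoints and means must align")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise InvalidInputError("smoothing_window must be odd and >= 1")
    if smoothing_window > 1:
        half = smoothing_window // 2
        sm = np.array(
            [y[max(0, i - half): i + half + 1].mean() for i in range(y.size)]
        )
    else:
        sm = y
    lo, hi = float(sm.min()), float(sm.max())
    if hi == lo:
        return PeakInterval(start=float(t[0]), end=float(t[-1]), flat=True)
    thresh = lo + top_fraction * (hi - lo)
    at_top = np.where(sm >= thresh - 1e-12 * max(1.0, abs(hi)))[0]
    return PeakInterval(start=float(t[at_top[0]]), end=float(t[at_top[-1]]))


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Bonferroni-adjusted pairwise comparisons."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, mean_diff, cohens_d, p_raw, p_adjusted
    n_comparisons: int


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni family-wise adjustment: min(1, m·p)."""
    return min(1.0, n_comparisons * p_raw)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    method: str = "anova_bonferroni",
) -> GroupComparison:
    """Compare >= 2 groups: one-way ANOVA, then pairwise tests with Bonferroni.

    ``method`` is ``anova_bonferroni`` (classic one-way ANOVA, pairwise
    two-sample t-tests, equal-variance) or ``t_test`` (pairwise only; the
    F/p fields then report the first pair's raw test).  Welch correction is
    off by default, matching the classic procedure.
    """
    if method not in ("anova_bonferroni", "t_test"):
        raise InvalidInputError(f"unknown method {method!r}")
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise InvalidInputError("need at least 2 groups")
    for k, a in arrays.items():
        if a.size < 2:
            raise InvalidInputError(f"group {k!r} has n < 2")
    if all(a.std(ddof=1) == 0 for a in arrays.values()):
        raise DegenerateVarianceError("zero within-group variance in every group")

    names = list(arrays)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    rows = []
    for a_name, b_name in pairs:
        a, b = arrays[a_name], arrays[b_name]
        with np.errstate(invalid="ignore"):
            t_stat, p_raw = stats.ttest_ind(a, b, equal_var=True)
        p_raw = 1.0 if math.isnan(p_raw) else float(p_raw)
        pooled = math.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
            / (a.size + b.size - 2)
        )
        d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        rows.append(
            {
                "group_a": a_name,
                "group_b": b_name,
                "mean_diff": float(a.mean() - b.mean()),
                "cohens_d": float(d),
                "p_raw": p_raw,
                "p_adjusted": bonferroni(p_raw, m),
            }
        )
    pairwise = pd.DataFrame(rows)
    if method == "anova_bonferroni":
        with np.errstate(invalid="ignore"):
            f_stat, p = stats.f_oneway(*arrays.values())
        f_stat = float(f_stat) if math.isfinite(f_stat) else 0.0
        p = float(p) if math.isfinite(p) else 1.0
    else:
        f_stat, p = float("nan"), float(pairwise["p_raw"].iloc[0])
    return GroupComparison(
        f_statistic=f_stat, p_value=p, pairwise=pairwise, n_comparisons=m
    )
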