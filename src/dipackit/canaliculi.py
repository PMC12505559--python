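"""Bile-canalicular secretion kinetics from ROI fluorescence traces.

Hepatocytes secrete the fluorogenic CMFDA product 5-CMF into bile canaliculi;
a confocal time series per canaliculus gives an intensity trace that rises
toward saturation. Two model-free readouts summarise each trace after baseline
subtraction and light smoothing:

* maximum amplitude — the peak baseline-corrected intensity (floored at 0);
* half-time — the first time the corrected trace reaches half of that
  amplitude, linearly interpolated between the bracketing samples. For a
  saturating exponential A(1 - exp(-k t)) this equals ln2/k.

An optional least-squares exponential fit is provided as a cross-check.
Group comparisons (amplitude, half-time, lumen area) are nonparametric:
Kruskal-Wallis across all groups plus pairwise two-sided Mann-Whitney tests
with BH adjustment, exact for small arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .deg import bh_adjust
from .containers import TraceSet

__all__ = [
    "preprocess_trace",
    "max_amplitude",
    "half_time",
    "fit_exponential",
    "summarize_kinetics",
    "equivalent_diameter",
    "compare_groups",
    "GroupComparison",
]


def preprocess_trace(
    intensity: np.ndarray, baseline_points: int = 3, smooth_window: int = 3
) -> tuple[np.ndarray, float]:
    """Baseline-subtract and smooth a raw intensity trace.

    The baseline is the mean of the first ``baseline_points`` samples; the
    corrected trace is smoothed with a centered moving average of odd width
    ``smooth_window`` whose window shrinks at the edges. Returns
    (corrected_smoothed, baseline).
    """
    intensity = np.asarray(intensity, dtype=float)
    if len(intensity) < baseline_points:
        raise ValueError("trace shorter than the number of baseline points")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    baseline = float(intensity[:baseline_points].mean())
    corrected = intensity - baseline
    if smooth_window == 1:
        return corrected, baseline
    smoothed = (
        pd.Series(corrected)
        .rolling(window=smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return smoothed, baseline


def max_amplitude(corrected: np.ndarray) -> float:
    """Maximum of the baseline-corrected trace, floored at zero."""
    return float(max(np.max(np.asarray(corrected, dtype=float)), 0.0))


def half_time(time: np.ndarray, corrected: np.ndarray) -> float:
    """First time the corrected trace reaches half its maximum amplitude.

    Linearly interpolates between the bracketing samples; returns NaN
    (undefined) when the amplitude is zero or the half level is never reached
    within the observation window.
    """
    time = np.asarray(time, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    amplitude = max_amplitude(corrected)
    if amplitude <= 0:
        return float("nan")
    target = amplitude / 2.0
    above = corrected >= target
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))  # first sample at/above the half level
    if i == 0:
        return float(time[0])
    y0, y1 = corrected[i - 1], corrected[i]
    if y1 == y0:
        return float(time[i])
    frac = (target - y0) / (y1 - y0)
    return float(time[i - 1] + frac * (time[i] - time[i - 1]))


def fit_exponential(
    time: np.ndarray, intensity: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of b + A(1 - exp(-k t)); returns (A, k, b).

    Cross-check for the interpolation-based half-time (ln2/k).
    """
    time = np.asarray(time, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    a0 = max(intensity.max() - intensity.min(), 1e-6)
    span = max(time[-1] - time[0], 1e-6)
    p0 = (a0, 1.0 / span, float(intensity[0]))
    popt, _ = optimize.curve_fit(
        lambda t, a, k, b: b + a * (1.0 - np.exp(-k * t)),
        time,
        intensity,
        p0=p0,
        bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def summarize_kinetics(
    traces: TraceSet, baseline_points: int = 3, smooth_window: int = 3
) -> pd.DataFrame:
    """Per-trace kinetics table: group, baseline, amplitude, half_time, area.

    ``half_time`` is NaN where undefined; ``area`` is NaN when no area table
    was supplied.
    """
    rows = []
    for tid in traces.trace_ids():
        t, raw = traces.get(tid)
        corrected, baseline = preprocess_trace(raw, baseline_points, smooth_window)
        amp = max_amplitude(corrected)
        rows.append(
            {
                "trace_id": tid,
                "group": traces.group_of(tid),
                "baseline": baseline,
                "amplitude": amp,
                "half_time": half_time(t, corrected),
                "area": (
                    float(traces.areas[tid])
                    if traces.areas is not None and tid in traces.areas.index
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows).set_index("trace_id")


def equivalent_diameter(area: float | np.ndarray) -> float | np.ndarray:
    """Diameter of the circle with the given area: 2 sqrt(area / pi)."""
    return 2.0 * np.sqrt(np.asarray(area, dtype=float) / np.pi)


@dataclass
class GroupComparison:
    """Nonparametric comparison of one kinetic metric across groups."""

    metric: str
    kruskal_p: float
    pairwise: pd.DataFrame  # group_a, group_b, n_a, n_b, u, pvalue, padj
    group_stats: pd.DataFrame  # n, median, iqr per group
    n_undefined_excluded: int


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # exact p for small untied arms, tie-corrected normal approximation otherwise
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(summaries: pd.DataFrame, metric: str) -> GroupComparison:
    """Kruskal-Wallis plus BH-adjusted pairwise Mann-Whitney on one metric.

    ``summaries`` is the output of :func:`summarize_kinetics` (or any table
    with ``group`` and the metric column). Traces with an undefined (NaN)
    metric are excluded, with the exclusion count reported. Requires at least
    two groups with >= 3 usable traces each.
    """
    if metric not in summaries.columns:
        raise ValueError(f"metric {metric!r} not in the summary table")
    values = summaries[["group", metric]].copy()
    n_undef = int(values[metric].isna().sum())
    values = values.dropna(subset=[metric])
    if values.empty:
        raise ValueError(f"metric {metric!r} missing for all traces")
    by_group = {
        g: sub[metric].to_numpy(dtype=float)
        for g, sub in values.groupby("group", sort=False)
    }
    usable = {g: v for g, v in by_group.items() if len(v) >= 3}
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 3 traces each")

    kw_p = float(stats.kruskal(*usable.values()).pvalue)
    groups = list(usable)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = groups[i], groups[j]
            u, p = _mannwhitney(usable[ga], usable[gb])
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(usable[ga]),
                    "n_b": len(usable[gb]),
                    "u": u,
                    "pvalue": p,
                }
            )
    pairwise = pd.DataFrame(rows)
    pairwise["padj"] = bh_adjust(pairwise["pvalue"].to_numpy())

    group_stats = pd.DataFrame(
        {
            g: {
                "n": len(v),
                "median": float(np.median(v)),
                "iqr": float(np.subtract(*np.percentile(v, [75, 25]))),
            }
            for g, v in usable.items()
        }
    ).T
    group_stats.index.name = "group"
    return GroupComparison(
        metric=metric,
        kruskal_p=kw_p,
        pairwise=pairwise,
        group_stats=group_stats,
        n_undefined_excluded=n_undef,
    )
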