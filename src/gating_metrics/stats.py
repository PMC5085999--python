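"""Windowed trajectory statistics, distributions and two-sample tests.

The reporting protocol used throughout is: time-average each subunit's
series over an analysis window (typically the last 10 ns of a 50-ns run),
then take the mean and sample SD (n−1) across the four subunit averages.
Windows are inclusive on both ends and select frames by time stamp, not by
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import MetricTimeSeries

__all__ = [
    "WindowStats",
    "Distribution",
    "window_mask",
    "window_average",
    "tetramer_stats",
    "histogram",
    "welch_test",
]


@dataclass
class WindowStats:
    group_values: list[float]
    mean: float
    sd: float
    n: int


@dataclass
class Distribution:
    bin_edges: np.ndarray
    frequencies: np.ndarray  # fractions summing to 1
    bin_size: float
    clipped: bool = False


def window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 < t0:
        raise ValueError(f"empty window [{t0}, {t1}]")
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise ValueError(f"window [{t0}, {t1}] selects no frames")
    return mask


def window_average(
    series: MetricTimeSeries, window: tuple[float, float]
) -> dict[str, float]:
    """Per-subunit arithmetic mean over frames with t_start <= t <= t_end."""
    mask = window_mask(series.times, window)
    return {c: float(v[mask].mean()) for c, v in series.per_subunit.items()}


def tetramer_stats(per_subunit_means) -> WindowStats:
    """Mean and sample SD (n−1) across subunit window-averages."""
    if isinstance(per_subunit_means, dict):
        values = [float(v) for v in per_subunit_means.values()]
    else:
        values = [float(v) for v in per_subunit_means]
    if len(values) < 2:
        raise ValueError("tetramer statistics need at least 2 group values")
    arr = np.array(values)
    return WindowStats(
        group_values=values,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=len(values),
    )


def histogram(
    values, bin_size: float, value_range: tuple[float, float]
) -> Distribution:
    """Fixed-bin-size histogram normalised to fractions.

    Bins are left-closed/right-open with the last bin closed.  Values
    outside ``value_range`` are clipped into the edge bins and flagged.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    lo, hi = value_range
    if hi <= lo:
        raise ValueError("empty value range")
    values = np.asarray(values, dtype=float).ravel()
    n_bins = int(np.ceil((hi - lo) / bin_size - 1e-9))
    edges = lo + bin_size * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)
    clipped = bool((values < lo).any() or (values > hi).any())
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=edges)
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return Distribution(
        bin_edges=edges, frequencies=freq, bin_size=bin_size, clipped=clipped
    )


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, dof, two-sided p).

    Degenerate input (both groups constant with equal means) returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    se_a, se_b = va / len(a), vb / len(b)
    dof = (se_a + se_b) ** 2 / (
        se_a**2 / (len(a) - 1) + se_b**2 / (len(b) - 1)
    )
    return float(res.statistic), float(dof), float(res.pvalue)
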