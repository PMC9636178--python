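"""Bootstrap-coupled estimation statistics and boxplot summaries.

Condition comparisons throughout the pipeline are reported as an observed
mean difference with a percentile bootstrap confidence interval (5000
resamples by default), in the estimation-statistics style, alongside the
standard boxplot five-number summary with 1.5*IQR whiskers and explicit
outlier listing (so tests can be run with and without outliers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EstimationResult:
    """Observed mean (or median) difference b - a with a bootstrap CI."""

    delta: float
    ci_low: float
    ci_high: float
    n_resamples: int
    paired: bool
    statistic: str = "mean"
    bootstrap_mean: float = float("nan")


def bootstrap_difference(a, b, paired: bool = False, n_resamples: int = 5000,
                         rng: np.random.Generator | None = None,
                         statistic: str = "mean") -> EstimationResult:
    """Bootstrap estimate of the difference ``stat(b) - stat(a)``.

    Paired comparisons resample index pairs; unpaired comparisons resample
    each group independently.  The CI is the 2.5/97.5 percentile of the
    resampled differences.  Deterministic under a fixed generator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if paired and a.size != b.size:
        raise ValueError(f"paired samples differ in length ({a.size}, {b.size})")
    rng = rng or np.random.default_rng(0)
    stat = np.mean if statistic == "mean" else np.median

    delta = float(stat(b) - stat(a))
    if paired:
        idx = rng.integers(0, a.size, (n_resamples, a.size))
        diffs = stat(b[idx], axis=1) - stat(a[idx], axis=1)
    else:
        idx_b = rng.integers(0, b.size, (n_resamples, b.size))
        idx_a = rng.integers(0, a.size, (n_resamples, a.size))
        diffs = stat(b[idx_b], axis=1) - stat(a[idx_a], axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return EstimationResult(delta, float(lo), float(hi), n_resamples, paired,
                            statistic, float(diffs.mean()))


@dataclass
class BoxplotStats:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_stats(x) -> BoxplotStats:
    """Five-number boxplot summary with 1.5*IQR whiskers.

    Quartiles use linear-interpolation quantiles; whiskers extend to the
    most extreme data within ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``; anything
    beyond is listed as an outlier.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxplotStats(float(q1), float(med), float(q3),
                        float(inside.min()), float(inside.max()),
                        np.sort(outliers))


def without_outliers(x) -> np.ndarray:
    """The sample with boxplot outliers removed (for the with/without
    significance-test convention)."""
    stats = boxplot_stats(x)
    x = np.asarray(x, dtype=float)
    return x[(x >= stats.whisker_low) & (x <= stats.whisker_high)]
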