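"""Windowed cfDNA fragment-size statistics.

Fragment size is a secondary rejection marker: graft apoptosis during
acute rejection shifts the circulating fragment-size distribution
upward.  Mean size is computed inside a closed measurement window
(default [40, 10000] bp, the instrument's sizing range), and the
baseline-vs-endpoint comparison is a paired one-tailed Student's
t-test for larger fragments at the endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_WINDOW",
    "WindowedMean",
    "PairedTResult",
    "mean_fragment_size",
    "compare_conditions",
]

DEFAULT_WINDOW: tuple[float, float] = (40.0, 10_000.0)


@dataclass(frozen=True)
class WindowedMean:
    mean: float  # NaN when no sizes fall inside the window
    n_used: int
    n_total: int

    @property
    def empty(self) -> bool:
        return self.n_used == 0


def mean_fragment_size(
    sizes: Sequence[float], window: tuple[float, float] = DEFAULT_WINDOW
) -> WindowedMean:
    """Arithmetic mean of fragment sizes within the closed window.

    An empty input, or one with every size outside the window, yields
    a flagged empty result (mean NaN) rather than 0.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"window min must be below max, got {window}")
    arr = np.asarray(sizes, dtype=float)
    if arr.ndim != 1:
        raise ValueError("sizes must be one-dimensional")
    in_window = arr[(arr >= lo) & (arr <= hi)]
    if len(in_window) == 0:
        return WindowedMean(mean=float("nan"), n_used=0, n_total=len(arr))
    return WindowedMean(
        mean=float(in_window.mean()), n_used=int(len(in_window)), n_total=len(arr)
    )


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p_one_tailed: float
    n: int
    mean_difference: float  # endpoint - baseline


def compare_conditions(
    baseline: Sequence[float], endpoint: Sequence[float]
) -> PairedTResult:
    """Paired one-tailed t-test for endpoint fragment sizes exceeding
    baseline (alternative: endpoint > baseline)."""
    b = np.asarray(baseline, dtype=float)
    e = np.asarray(endpoint, dtype=float)
    if b.shape != e.shape or b.ndim != 1:
        raise ValueError("baseline and endpoint must be equal-length 1-D vectors")
    if len(b) < 2:
        raise ValueError("paired t-test requires n >= 2")
    diff = e - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t-test undefined")
    res = stats.ttest_rel(e, b, alternative="greater")
    return PairedTResult(
        t=float(res.statistic),
        p_one_tailed=float(res.pvalue),
        n=len(b),
        mean_difference=float(diff.mean()),
    )
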