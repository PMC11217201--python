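"""Accuracy, test-retest repeatability, agreement and QC statistics.

The protocol's analysis stage: absolute flow-value error against the
reference flow Qref, relative test-retest repeatability error, summary
statistics, threshold counting, Bland-Altman limits of agreement,
least-squares correlation lines, and the two quality-control checks
(flow-meter conservation Qcyl + Qtube vs Qpump, and injected activity vs
the requested 500 MBq, both against the 15% limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurement",
    "SummaryStats",
    "BlandAltmanResult",
    "QCResult",
    "flow_value_error",
    "repeatability_error",
    "summarize",
    "count_exceeding",
    "bland_altman",
    "linear_fit",
    "flowmeter_qc",
    "activity_qc",
]


@dataclass(frozen=True)
class PairedMeasurement:
    """One test-retest pair (flow in ml/min, or activity in MBq)."""

    measurement_id: str   # e.g. "150-20"
    system: str           # e.g. "DMI-20" or "Vision-600"
    test_value: float
    retest_value: float
    quantity: str = ""    # e.g. "Qin", "Qout", "activity"


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: Optional[float]   # sample SD (n-1); None for n = 1


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class QCResult:
    observed_percent: float
    limit_percent: float

    @property
    def passed(self) -> bool:
        return abs(self.observed_percent) <= self.limit_percent


def flow_value_error(flow: float, qref: float) -> float:
    """Absolute flow-value error in percent: 100 |flow - Qref| / Qref."""
    if qref <= 0:
        raise ValueError(f"Qref must be positive, got {qref}")
    return abs((flow - qref) / qref) * 100.0


def repeatability_error(test: float, retest: float, signed: bool = False) -> float:
    """Test-retest repeatability error in percent: 100 (retest - test) / test.

    Absolute value by default; ``signed=True`` returns the signed relative
    difference (the convention of the injected-activity table).
    """
    if test == 0:
        raise ValueError("repeatability error undefined for test value 0")
    err = (retest - test) / test * 100.0
    return err if signed else abs(err)


def summarize(values: Sequence[float]) -> SummaryStats:
    """Arithmetic mean and sample standard deviation (n - 1 denominator)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return SummaryStats(n=int(arr.size), mean=float(np.mean(arr)), sd=sd)


def count_exceeding(values: Sequence[float], threshold_percent: float) -> int:
    """Number of values strictly greater than the threshold."""
    if threshold_percent < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold_percent}")
    arr = np.asarray(list(values), dtype=float)
    return int(np.sum(arr > threshold_percent))


def bland_altman(values_a: Sequence[float], values_b: Sequence[float]) -> BlandAltmanResult:
    """Agreement between paired series: differences a - b, LoA = mean +- 1.96 SD."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired series must have equal length ({a.size} vs {b.size})")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diff = a - b
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(
        n=int(a.size),
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Ordinary least-squares line and Pearson r: returns (slope, intercept, r)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length series with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; line is undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def flowmeter_qc(
    qcyl_measured: float, qtube_measured: float, qpump: float, limit_percent: float = 15.0
) -> QCResult:
    """Flow conservation check: 100 (Qcyl + Qtube - Qpump) / Qpump vs the limit."""
    if qpump <= 0:
        raise ValueError(f"Qpump must be positive, got {qpump}")
    observed = (qcyl_measured + qtube_measured - qpump) / qpump * 100.0
    return QCResult(observed_percent=float(observed), limit_percent=limit_percent)


def activity_qc(
    injected_MBq: float, requested_MBq: float = 500.0, limit_percent: float = 15.0
) -> QCResult:
    """Injected-activity check: 100 |injected - requested| / requested vs the limit."""
    if requested_MBq <= 0:
        raise ValueError(f"requested activity must be positive, got {requested_MBq}")
    observed = abs(injected_MBq - requested_MBq) / requested_MBq * 100.0
    return QCResult(observed_percent=float(observed), limit_percent=limit_percent)
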