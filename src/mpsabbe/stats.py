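"""Replicate-run aggregation and two-sample comparison statistics.

Experimental arms are summarized as (mean, sd, n) and compared with the
pooled-standard-error two-sample statistic

    t = (μ_a − μ_b) / sqrt(s_a²/n_a + s_b²/n_b)

against a one-sided critical value (1.645, the normal 5% quantile, by
default; an exact Student-t quantile with df = n_a + n_b − 2 is
available).  Improvement of a candidate mean over a reference is
reported as 100·(μ_ref − μ_new)/|μ_ref|, positive when the candidate
found a lower energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "two_sample_t",
    "improvement_percent",
    "summarize_runs",
]

ONE_SIDED_CRITICAL = 1.645  # standard-normal 95% quantile


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise ValueError(f"sd must be finite and non-negative, got {self.sd}")


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    critical_value: float
    reject_null: bool


def two_sample_t(
    a: GroupSummary,
    b: GroupSummary,
    critical_value: float = ONE_SIDED_CRITICAL,
    exact_quantile: bool = False,
    alpha: float = 0.05,
) -> TestResult:
    """One-sided two-sample comparison of summarized groups.

    ``exact_quantile`` replaces the z-type critical value with the
    Student-t quantile at df = n_a + n_b − 2.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both groups have zero variance")
    t = (a.mean - b.mean) / math.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
    crit = (
        float(sps.t.ppf(1 - alpha, df=a.n + b.n - 2))
        if exact_quantile
        else critical_value
    )
    return TestResult(t_statistic=t, critical_value=crit, reject_null=t > crit)


def improvement_percent(mean_new: float, mean_ref: float) -> float:
    """100·(μ_ref − μ_new)/|μ_ref|; positive = the new method is lower."""
    if mean_ref == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_ref - mean_new) / abs(mean_ref)


def summarize_runs(
    results: Iterable, label: str = "", key: str = "best_energy"
) -> GroupSummary:
    """(mean, sample sd, n) of an attribute over replicate PhaseResults.

    Accepts raw numbers as well; sample sd uses the n−1 denominator.
    """
    values = [
        float(getattr(r, key)) if hasattr(r, key) else float(r) for r in results
    ]
    if len(values) < 2:
        raise ValueError("need at least 2 results")
    arr = np.asarray(values)
    return GroupSummary(
        label=label,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=len(values),
    )
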