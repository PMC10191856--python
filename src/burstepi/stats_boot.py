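"""Bootstrap hypothesis testing, Fisher's exact test, and error propagation.

The two-sample bootstrap test enforces the null by translating both groups
to the pooled mean, resamples each group with replacement, and reports the
two-sided achieved significance level (ASL) with add-one Monte-Carlo
smoothing, ``(1 + #{|d*| >= |d_obs|}) / (B + 1)``, so that p-values are
never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TestResult", "bootstrap_asl_test", "fisher_active", "propagate_ratio"]


@dataclass
class TestResult:
    statistic: float
    asl: float                # achieved significance level (p-value)
    n_boot: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.asl <= 1.0:
            raise ValueError("ASL must lie in [0, 1]")


def _group_stat(x: np.ndarray, axis: int = -1, studentized: bool = False):
    if studentized:
        n = x.shape[axis]
        return x.mean(axis=axis), x.var(axis=axis, ddof=1) / n
    return x.mean(axis=axis), None


def bootstrap_asl_test(
    a,
    b,
    n_boot: int = 10_000,
    seed: int = 0,
    studentized: bool = False,
    batch: int = 2000,
) -> TestResult:
    """Two-sided two-sample bootstrap hypothesis test.

    The observed statistic is ``mean(a) - mean(b)`` (or its studentized
    version); the null is imposed by shifting each group to the pooled
    mean before resampling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled_mean = np.concatenate([a, b]).mean()
    d_obs = a.mean() - b.mean()
    if studentized:
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        d_obs = d_obs / se if se > 0 else (0.0 if d_obs == 0 else np.inf)
    a0 = a - a.mean() + pooled_mean
    b0 = b - b.mean() + pooled_mean
    if np.ptp(np.concatenate([a0, b0])) == 0:
        asl = 1.0 if d_obs == 0 else 1.0 / (n_boot + 1)
        return TestResult(float(d_obs), asl, n_boot, "bootstrap-degenerate")

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_boot:
        m = min(batch, n_boot - done)
        ra = a0[rng.integers(0, a.size, size=(m, a.size))]
        rb = b0[rng.integers(0, b.size, size=(m, b.size))]
        d = ra.mean(axis=1) - rb.mean(axis=1)
        if studentized:
            se = np.sqrt(ra.var(axis=1, ddof=1) / a.size + rb.var(axis=1, ddof=1) / b.size)
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.where(se > 0, d / se, 0.0)
        exceed += int(np.sum(np.abs(d) >= abs(d_obs)))
        done += m
    asl = (1 + exceed) / (n_boot + 1)
    method = "bootstrap-studentized" if studentized else "bootstrap-mean"
    return TestResult(float(d_obs), float(asl), n_boot, method)


def fisher_active(
    n_active_1: int,
    n_inactive_1: int,
    n_active_2: int,
    n_inactive_2: int,
) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 active/inactive table."""
    table = [[n_active_1, n_inactive_1], [n_active_2, n_inactive_2]]
    if min(min(row) for row in table) < 0:
        raise ValueError("counts must be non-negative")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), 0, "fisher-exact")


def propagate_ratio(x: float, sd_x: float, y: float, sd_y: float):
    """Ratio ``x / y`` with first-order error propagation for independent
    measurements: ``sd = sqrt((sd_x / y)^2 + (x sd_y / y^2)^2)``."""
    if y == 0:
        raise ZeroDivisionError("ratio undefined for y = 0")
    if sd_x < 0 or sd_y < 0:
        raise ValueError("standard deviations must be >= 0")
    r = x / y
    sd = np.hypot(sd_x / y, x * sd_y / y**2)
    return float(r), float(sd)
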