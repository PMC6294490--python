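"""Cohort statistics: summaries, fold-changes and the resampling test.

Replication delays are compared between strains with a two-sample Monte
Carlo resampling (label-permutation) test on the difference of cohort
means: the per-cell delta_t values of both cohorts are pooled, labels are
reshuffled preserving group sizes, and the achieved significance is

    p = (#{ |resampled diff| >= |observed diff| } + 1) / (n_iterations + 1),

two-sided by default, with the add-one correction so p is never exactly 0.
The default iteration count is 1,000,000 as used for the reported
comparisons; smaller counts with fixed seeds are appropriate for tests.
A bootstrap variant (both groups resampled with replacement from the pool)
is available for sensitivity analysis.  No multiple-testing correction is
applied by default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import ReplicationEvent

__all__ = [
    "CohortResult",
    "ResamplingTestResult",
    "summarize_cohort",
    "resampling_test",
    "fold_change",
    "significance_stars",
    "benjamini_hochberg",
]

#: star-notation thresholds used in the figure legends
STAR_THRESHOLDS = (0.05, 0.005, 0.0005, 0.00005)


@dataclass
class CohortResult:
    """Summary of one strain/scenario cohort."""

    label: str
    n: int
    mean_delta_t: float
    sem: float
    mean_rate: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    delta_t: np.ndarray  # the underlying per-cell values


def _deltas(events) -> np.ndarray:
    if len(events) and isinstance(events[0], ReplicationEvent):
        return np.array([ev.delta_t for ev in events], dtype=float)
    return np.asarray(events, dtype=float)


def summarize_cohort(events, label: str = "", bin_width: float = 2.0) -> CohortResult:
    """Mean, SEM and histogram of a cohort of replication delays.

    Accepts ReplicationEvents (their delta_t is used) or a plain array of
    delays.  SEM is the sample standard deviation (n-1 denominator) over
    sqrt(n); the histogram uses fixed-width bins anchored at 0.
    """
    x = _deltas(events)
    if x.size < 2:
        raise ValueError("need at least 2 events to summarize a cohort")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite delta_t in cohort")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    lo = np.floor(x.min() / bin_width) * bin_width
    lo = min(lo, 0.0)
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    rate = np.nan
    if len(events) and isinstance(events[0], ReplicationEvent):
        rates = np.array([ev.rate for ev in events], dtype=float)
        if np.all(np.isfinite(rates)):
            rate = float(rates.mean())
    return CohortResult(
        label=label, n=int(x.size), mean_delta_t=mean, sem=sem, mean_rate=rate,
        hist_edges=edges, hist_counts=counts, delta_t=x,
    )


@dataclass
class ResamplingTestResult:
    observed_diff: float  # mean(A) - mean(B), minutes
    n_iterations: int
    p_value: float
    two_sided: bool
    seed: int | None
    method: str = "permutation"
    n_exceed: int = 0


def resampling_test(
    cohort_a,
    cohort_b,
    n_iterations: int = 1_000_000,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    two_sided: bool = True,
    method: str = "permutation",
    batch_size: int = 100_000,
) -> ResamplingTestResult:
    """Monte Carlo resampling test on the difference of cohort means.

    ``method="permutation"`` reshuffles the pooled values into groups of
    the original sizes; ``method="bootstrap"`` draws both groups with
    replacement from the pool.  The p-value carries the add-one correction,
    p = (n_exceed + 1)/(n_iterations + 1), so it lies in (0, 1].

    Accepts cohorts as ReplicationEvent lists, plain arrays, or
    CohortResults.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if method not in ("permutation", "bootstrap"):
        raise ValueError("method must be 'permutation' or 'bootstrap'")
    a = cohort_a.delta_t if isinstance(cohort_a, CohortResult) else _deltas(cohort_a)
    b = cohort_b.delta_t if isinstance(cohort_b, CohortResult) else _deltas(cohort_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both cohorts must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = float(a.mean() - b.mean())
    crit = abs(obs) if two_sided else obs
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    if two_sided:
        # canonical form: |mean difference| depends only on the pooled
        # multiset and the (unordered) group sizes, so sorting the pool and
        # resampling the smaller group makes A<->B label swaps bit-identical
        pooled = np.sort(pooled)
        na = min(na, n - na)
    # tolerance so exact ties (e.g. integer data) count as exceedances
    tol = 1e-9 * max(1.0, float(np.abs(pooled).max()))
    n_exceed = 0
    remaining = n_iterations
    while remaining > 0:
        m = min(batch_size, remaining)
        if method == "permutation":
            block = np.broadcast_to(pooled, (m, n)).copy()
            rng.permuted(block, axis=1, out=block)
            diffs = block[:, :na].mean(axis=1) - block[:, na:].mean(axis=1)
        else:
            ia = rng.integers(0, n, size=(m, na))
            ib = rng.integers(0, n, size=(m, n - na))
            diffs = pooled[ia].mean(axis=1) - pooled[ib].mean(axis=1)
        if two_sided:
            n_exceed += int((np.abs(diffs) >= crit - tol).sum())
        else:
            n_exceed += int((diffs >= crit - tol).sum())
        remaining -= m
    p = (n_exceed + 1) / (n_iterations + 1)
    return ResamplingTestResult(
        observed_diff=obs, n_iterations=n_iterations, p_value=float(p),
        two_sided=two_sided, seed=seed, method=method, n_exceed=n_exceed,
    )


def fold_change(reference: CohortResult, test: CohortResult) -> dict:
    """Fold-slowdown of the test cohort relative to the reference.

    Since rate is inversely proportional to delta_t over a fixed distance,
    the delta_t ratio mean(test)/mean(reference) equals the fold-decrease
    in replication rate; the percent rate reduction is
    100 (1 - rate_test/rate_ref) = 100 (1 - mean_ref/mean_test).
    """
    if reference.mean_delta_t <= 0 or test.mean_delta_t <= 0:
        raise ValueError("cohort means must be positive")
    ratio = test.mean_delta_t / reference.mean_delta_t
    return {
        "delta_t_ratio": ratio,
        "rate_fold_decrease": ratio,
        "percent_rate_reduction": 100.0 * (1.0 - 1.0 / ratio),
    }


def bootstrap_ratio_ci(
    reference,
    test,
    *,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the delta_t ratio mean(test)/mean(ref)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    a = reference.delta_t if isinstance(reference, CohortResult) else _deltas(reference)
    b = test.delta_t if isinstance(test, CohortResult) else _deltas(test)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    ratios = b[ib].mean(axis=1) / a[ia].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(ratios, alpha)), float(np.quantile(ratios, 1 - alpha)))


def significance_stars(p: float) -> str:
    """Star notation at the legend thresholds 0.05/0.005/0.0005/0.00005."""
    return "*" * sum(p < thr for thr in STAR_THRESHOLDS)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out
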