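"""Minimum combination t-test for spatial growth-rate heterogeneity.

The procedure asks, per patient: could the per-nodule change rates plausibly
all share one mean?  It splits the patient's n nodules into two groups of
near-equal size (sizes floor(n/2) and ceil(n/2)) in every possible way — a
split and its mirror give the same two-sided t-test, so complementary
even-n splits are counted once — runs a two-sample t-test on each split's
change rates, and takes the minimum p-value over all splits.  If that
minimum falls below the significance level (default 0.05) the homogeneity
null is rejected.  Doing this on the diameter rates and the volume rates
and taking min(min(p)) gives the overall per-patient verdict.

When the number of distinct balanced splits exceeds a cap (default 4000),
a uniform random sample of ``cap`` distinct splits is evaluated instead,
reproducibly under an explicit seed.

Note the statistic is a minimum over many correlated tests with no
multiplicity correction, so it is anti-conservative by construction: under
a homogeneous null its rejection rate exceeds the nominal level and grows
with n.  The simulation harness measures this; see the methods note.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Metric, PatientSeries, change_records

__all__ = [
    "DEFAULT_CAP",
    "DEFAULT_ALPHA",
    "TooFewLesionsError",
    "TVariant",
    "BipartitionScheme",
    "HeterogeneityResult",
    "count_balanced_bipartitions",
    "bipartitions",
    "two_sample_p",
    "min_combination_p",
    "assess_heterogeneity",
    "overall_verdict",
    "write_heterogeneity_report",
]

DEFAULT_CAP = 4000
DEFAULT_ALPHA = 0.05

# relative tolerance for "zero variance" / "equal means" degenerate calls
_DEGENERATE_RTOL = 1e-12


class TooFewLesionsError(ValueError):
    """The combination test needs at least 4 lesions."""


class TVariant(str, enum.Enum):
    POOLED = "pooled"
    WELCH = "welch"


@dataclass(frozen=True)
class BipartitionScheme:
    """The set of balanced two-group splits evaluated for one patient."""

    n_items: int
    group_sizes: tuple[int, int]
    n_total_partitions: int
    cap: int
    evaluated_partitions: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    sampling_seed: int | None = None

    @property
    def sampled(self) -> bool:
        return self.n_total_partitions > self.cap


@dataclass(frozen=True)
class HeterogeneityResult:
    """Per-patient verdict: minimum p per metric and the overall min(min(p))."""

    patient_id: str
    min_p_diameter: float
    min_p_volume: float
    alpha: float = DEFAULT_ALPHA
    argmin_partition_diameter: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    argmin_partition_volume: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    degenerate_triggered: bool = field(default=False)

    @property
    def min_min_p(self) -> float:
        return min(self.min_p_diameter, self.min_p_volume)

    @property
    def heterogeneous(self) -> bool:
        return self.min_min_p < self.alpha


def count_balanced_bipartitions(n: int) -> int:
    """Number of distinct splits of n items into groups of floor/ceil(n/2).

    Odd n: C(n, n//2) — group sizes differ, so no complement duplicates.
    Even n: C(n, n/2) // 2 — a split and its complement are the same
    partition.  31 items give C(31,15) = 300,540,195.
    """
    if n < 4:
        raise TooFewLesionsError(f"need at least 4 lesions, got {n}")
    k = n // 2
    total = math.comb(n, k)
    return total // 2 if n % 2 == 0 else total


def _partition_from_first(n: int, first: tuple[int, ...]):
    rest = tuple(i for i in range(n) if i not in set(first))
    return (first, rest)


def bipartitions(
    n: int,
    cap: int = DEFAULT_CAP,
    seed: int | None = None,
) -> BipartitionScheme:
    """Enumerate (or uniformly sample, beyond ``cap``) balanced bipartitions.

    Full deduplicated enumeration when the total count is <= cap; otherwise
    ``cap`` distinct partitions are drawn uniformly without replacement using
    ``seed``.  Partitions are index-set pairs over range(n), first group of
    size floor(n/2).
    """
    if n < 4:
        raise TooFewLesionsError(f"need at least 4 lesions, got {n}")
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    k = n // 2
    total = count_balanced_bipartitions(n)
    parts: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    if total <= cap:
        for comb in combinations(range(n), k):
            # even n: keep only splits whose first group contains item 0 —
            # exactly one representative per complement pair
            if n % 2 == 0 and comb[0] != 0:
                continue
            parts.append(_partition_from_first(n, comb))
    else:
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, ...]] = set()
        all_items = frozenset(range(n))
        while len(parts) < cap:
            # batch draws: random k-subsets as the first k slots of random
            # permutations, canonicalized (even n: representative contains 0)
            batch = rng.random((max(cap - len(parts), 64) * 2, n)).argsort(axis=1)[:, :k]
            batch.sort(axis=1)
            for row in batch:
                group = tuple(int(i) for i in row)
                if n % 2 == 0 and group[0] != 0:
                    group = tuple(sorted(all_items - set(group)))
                if group in seen:
                    continue
                seen.add(group)
                parts.append(_partition_from_first(n, group))
                if len(parts) == cap:
                    break
    return BipartitionScheme(
        n_items=n,
        group_sizes=(k, n - k),
        n_total_partitions=total,
        cap=cap,
        evaluated_partitions=tuple(parts),
        sampling_seed=seed if total > cap else None,
    )


def _t_and_p(
    mean_a, mean_b, var_a, var_b, n_a: int, n_b: int, variant: TVariant
):
    """Vectorized two-sided two-sample t-test; arrays or scalars.

    Degenerate conventions: both variances zero -> p = 1 when means are
    equal, p = 0 when they differ (the groups are perfectly separated).
    """
    mean_a, mean_b = np.asarray(mean_a, float), np.asarray(mean_b, float)
    var_a = np.maximum(np.asarray(var_a, float), 0.0)
    var_b = np.maximum(np.asarray(var_b, float), 0.0)
    scale = np.maximum(np.abs(mean_a), np.abs(mean_b)) + 1.0
    if variant is TVariant.POOLED:
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
        df = np.broadcast_to(float(n_a + n_b - 2), se2.shape).copy()
    else:
        ta, tb = var_a / n_a, var_b / n_b
        se2 = ta + tb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (ta**2 / (n_a - 1) + tb**2 / (n_b - 1))
        df = np.where(np.isfinite(df), df, 1.0)
    degenerate = se2 <= (_DEGENERATE_RTOL * scale) ** 2
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    equal_means = np.abs(diff) <= _DEGENERATE_RTOL * scale
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    t_sep = np.where(diff > 0, np.inf, -np.inf)
    t = np.where(degenerate, np.where(equal_means, 0.0, t_sep), t)
    return t, p, bool(np.any(degenerate))


def two_sample_p(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: TVariant = TVariant.POOLED,
) -> float:
    """Two-sided two-sample t-test p-value on change rates.

    ``variant`` selects pooled-variance Student's t (default) or Welch.
    Both groups must have at least 2 observations.  Zero-variance groups
    follow the degenerate conventions documented in :func:`_t_and_p`.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise TooFewLesionsError(
            f"each group needs >= 2 values, got {a.size} and {b.size}"
        )
    _, p, _ = _t_and_p(
        a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1),
        a.size, b.size, TVariant(variant),
    )
    return float(p)


def min_combination_p(
    rates: Sequence[float],
    cap: int = DEFAULT_CAP,
    seed: int | None = None,
    variant: TVariant = TVariant.POOLED,
    scheme: BipartitionScheme | None = None,
):
    """Minimum two-sided t-test p-value over balanced bipartitions of ``rates``.

    Returns ``(min_p, argmin_partition, degenerate_triggered)``.  Supplying a
    precomputed ``scheme`` lets both metrics of one patient share splits.
    """
    x = np.asarray(rates, float)
    n = x.size
    if scheme is None:
        scheme = bipartitions(n, cap=cap, seed=seed)
    elif scheme.n_items != n:
        raise ValueError("scheme was built for a different number of items")
    variant = TVariant(variant)
    k, m = scheme.group_sizes
    idx_a = np.array([p[0] for p in scheme.evaluated_partitions], dtype=np.intp)
    xa = x[idx_a]  # (n_partitions, k)
    sum_all, ssq_all = x.sum(), (x * x).sum()
    sum_a, ssq_a = xa.sum(axis=1), (xa * xa).sum(axis=1)
    mean_a = sum_a / k
    mean_b = (sum_all - sum_a) / m
    var_a = (ssq_a - k * mean_a**2) / (k - 1)
    var_b = ((ssq_all - ssq_a) - m * mean_b**2) / (m - 1)
    _, p, degen = _t_and_p(mean_a, mean_b, var_a, var_b, k, m, variant)
    i = int(np.argmin(p))
    return float(p[i]), scheme.evaluated_partitions[i], degen


def assess_heterogeneity(
    series: PatientSeries,
    alpha: float = DEFAULT_ALPHA,
    cap: int = DEFAULT_CAP,
    seed: int | None = None,
    variant: TVariant = TVariant.POOLED,
) -> HeterogeneityResult:
    """Run the combination test on both metrics and combine the verdicts.

    Both metrics are evaluated over the same set of splits (one scheme per
    patient), so the overall min(min(p)) compares like with like.
    """
    if series.n_nodules < 4:
        raise TooFewLesionsError(
            f"patient {series.patient_id!r}: combination test needs >= 4 "
            f"nodules, got {series.n_nodules}"
        )
    scheme = bipartitions(series.n_nodules, cap=cap, seed=seed)
    d_rates = [r.rate_percent for r in change_records(series, Metric.DIAMETER)]
    v_rates = [r.rate_percent for r in change_records(series, Metric.VOLUME)]
    p_d, arg_d, deg_d = min_combination_p(d_rates, variant=variant, scheme=scheme)
    p_v, arg_v, deg_v = min_combination_p(v_rates, variant=variant, scheme=scheme)
    return HeterogeneityResult(
        patient_id=series.patient_id,
        min_p_diameter=p_d,
        min_p_volume=p_v,
        alpha=alpha,
        argmin_partition_diameter=arg_d,
        argmin_partition_volume=arg_v,
        degenerate_triggered=deg_d or deg_v,
    )


def overall_verdict(
    min_p_diameter: float, min_p_volume: float, alpha: float = DEFAULT_ALPHA
) -> tuple[float, bool]:
    """The study's decision rule on a pair of per-metric minimum p-values."""
    mm = min(min_p_diameter, min_p_volume)
    return mm, mm < alpha


def write_heterogeneity_report(results: Sequence[HeterogeneityResult], path, n_nodules=None) -> None:
    """Emit the per-patient report: min p per metric (4 decimals), the overall
    minimum, and a Yes/No heterogeneity verdict."""
    import pandas as pd

    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "patient_id": r.patient_id,
                **({"n_nodules": n_nodules[i]} if n_nodules is not None else {}),
                "min_p_diameter": round(r.min_p_diameter, 4),
                "min_p_volume": round(r.min_p_volume, 4),
                "min_min_p": round(r.min_min_p, 4),
                "heterogeneous": "Yes" if r.heterogeneous else "No",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
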