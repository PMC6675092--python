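"""Operating characteristics of the minimum combination t-test, by simulation.

The minimum-p statistic takes the smallest p-value over every balanced
bipartition without multiplicity correction, so its null rejection rate is
not the nominal level: it is anti-conservative, increasingly so as the
number of evaluated splits grows with n.  This harness measures two things
on synthetic cohorts:

- the empirical type-I rate under homogeneous growth (one normal component),
  per nodule count — the anti-conservativeness curve; and
- the detection rate (power) on two-subgroup patients whose subgroup means
  are well separated relative to the within-subgroup spread.

Both run the full pipeline path (measurement generation -> change rates ->
combination test), not a shortcut on raw rates.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .heterogeneity import DEFAULT_ALPHA, DEFAULT_CAP, TVariant, assess_heterogeneity
from .simulate import SimulationConfig, generate_patient

__all__ = ["null_rejection_rate", "null_rejection_curve", "detection_rate"]


def _base_config(n_nodules: int, seed: int, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        n_patients=1,
        nodules_min=n_nodules,
        nodules_max=n_nodules,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_rejection_rate(
    n_nodules: int,
    n_replicates: int = 400,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    cap: int = DEFAULT_CAP,
    measurement_cv: float = 0.02,
    rate_noise_sd_percent: float = 10.0,
    variant: TVariant = TVariant.POOLED,
) -> float:
    """Fraction of homogeneous patients whose diameter min-p falls below alpha.

    All nodules share one growth-rate distribution, so every rejection is a
    false positive of the single-metric minimum-p statistic.
    """
    cfg = _base_config(
        n_nodules,
        seed,
        measurement_cv=measurement_cv,
        rate_noise_sd_percent=rate_noise_sd_percent,
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_replicates):
        series, _ = generate_patient(cfg, heterogeneous=False, rng=rng)
        res = assess_heterogeneity(
            series, alpha=alpha, cap=cap, seed=int(rng.integers(2**31)), variant=variant
        )
        hits += res.min_p_diameter < alpha
    return hits / n_replicates


def null_rejection_curve(
    nodule_counts=(6, 8, 12, 16),
    n_replicates: int = 400,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Anti-conservativeness curve: null rejection rate per nodule count."""
    rows = []
    for j, n in enumerate(nodule_counts):
        rate = null_rejection_rate(n, n_replicates, seed=seed + j, **kwargs)
        rows.append({"n_nodules": n, "n_replicates": n_replicates,
                     "null_rejection_rate": rate})
    return pd.DataFrame(rows)


def detection_rate(
    n_nodules: int = 12,
    n_replicates: int = 500,
    seed: int = 0,
    subgroup_delta_percent: float = 30.0,
    rate_noise_sd_percent: float = 10.0,
    measurement_cv: float = 0.02,
    subgroup_fraction: float = 0.5,
    alpha: float = DEFAULT_ALPHA,
    cap: int = DEFAULT_CAP,
    variant: TVariant = TVariant.POOLED,
) -> float:
    """Fraction of two-subgroup patients flagged heterogeneous overall.

    Defaults place the subgroup means 3 within-subgroup SDs apart with six
    nodules per subgroup and 2% measurement noise.
    """
    cfg = _base_config(
        n_nodules,
        seed,
        growth_model="two_subgroup",
        subgroup_delta_percent=subgroup_delta_percent,
        rate_noise_sd_percent=rate_noise_sd_percent,
        measurement_cv=measurement_cv,
        subgroup_fraction=subgroup_fraction,
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_replicates):
        series, _ = generate_patient(cfg, heterogeneous=True, rng=rng)
        res = assess_heterogeneity(
            series, alpha=alpha, cap=cap, seed=int(rng.integers(2**31)), variant=variant
        )
        hits += res.heterogeneous
    return hits / n_replicates
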