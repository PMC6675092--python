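"""Paired agreement analyses between selection modes and between metrics.

Four contrasts of per-patient change rates are of interest: two-largest vs
all nodules on each metric, and diameter vs volume under each selection
mode.  Each contrast gets a paired t-test (two-sided, n-1 df on the
differences) and Bland-Altman limits of agreement, mean difference
+/- 1.96 * sample SD of the differences.  Differences are oriented
second - first, with first = the two-largest (resp. diameter) member of the
contrast; this is the orientation that reproduces the study's published
limits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Contrast",
    "PairedSample",
    "AgreementResult",
    "paired_t",
    "bland_altman",
    "contrasts_from_response_table",
    "agreement_frame",
    "write_agreement_report",
]

Z_95 = 1.96


class Contrast(str, enum.Enum):
    TWO_VS_ALL_DIAMETER = "two_vs_all_diameter"
    TWO_VS_ALL_VOLUME = "two_vs_all_volume"
    DIAM_VS_VOL_TWO = "diam_vs_vol_two"
    DIAM_VS_VOL_ALL = "diam_vs_vol_all"


@dataclass(frozen=True)
class PairedSample:
    """Equal-length per-patient change rates (%) for one contrast."""

    labels: tuple[str, ...]
    first: tuple[float, ...]
    second: tuple[float, ...]
    contrast: Contrast

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.first) == len(self.second)):
            raise ValueError("labels, first and second must have equal length")
        if len(self.first) < 3:
            raise ValueError(f"paired analysis needs n >= 3, got {len(self.first)}")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.second, float) - np.asarray(self.first, float)


@dataclass(frozen=True)
class AgreementResult:
    contrast: Contrast
    n: int
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def paired_t(sample: PairedSample) -> tuple[float, float]:
    """Two-sided paired t-test on second - first differences.

    Zero-variance differences are degenerate: all-zero -> (0, 1); constant
    nonzero -> (+/-inf, 0).
    """
    d = sample.differences
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return (np.inf if d[0] > 0 else -np.inf), 0.0
    t, p = stats.ttest_rel(sample.second, sample.first)
    return float(t), float(p)


def bland_altman(sample: PairedSample) -> AgreementResult:
    """Limits of agreement: mean difference +/- 1.96 sample SD (ddof=1)."""
    d = sample.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    t, p = paired_t(sample)
    return AgreementResult(
        contrast=sample.contrast,
        n=d.size,
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - Z_95 * sd,
        loa_high=mean + Z_95 * sd,
        t_statistic=t,
        p_value=p,
        degenerate=not np.isfinite(t),
    )


def contrasts_from_response_table(table: pd.DataFrame) -> dict[Contrast, PairedSample]:
    """Build the four study contrasts from a tidy response table.

    Expects one row per patient x mode with columns ``patient_id``, ``mode``
    (two_largest / all), ``diam_change_percent`` and ``vol_change_percent``
    — the shape produced by :func:`pulmhet.response.assess_cohort` and by
    the packaged study fixture.
    """
    two = table[table["mode"] == "two_largest"].set_index("patient_id")
    allr = table[table["mode"] == "all"].set_index("patient_id")
    if not two.index.equals(allr.index):
        raise ValueError("two_largest and all rows must cover the same patients")
    labels = tuple(str(i) for i in two.index)
    d2 = tuple(float(x) for x in two["diam_change_percent"])
    da = tuple(float(x) for x in allr["diam_change_percent"])
    v2 = tuple(float(x) for x in two["vol_change_percent"])
    va = tuple(float(x) for x in allr["vol_change_percent"])
    return {
        Contrast.TWO_VS_ALL_DIAMETER: PairedSample(labels, d2, da, Contrast.TWO_VS_ALL_DIAMETER),
        Contrast.TWO_VS_ALL_VOLUME: PairedSample(labels, v2, va, Contrast.TWO_VS_ALL_VOLUME),
        Contrast.DIAM_VS_VOL_TWO: PairedSample(labels, d2, v2, Contrast.DIAM_VS_VOL_TWO),
        Contrast.DIAM_VS_VOL_ALL: PairedSample(labels, da, va, Contrast.DIAM_VS_VOL_ALL),
    }


def agreement_frame(table: pd.DataFrame) -> pd.DataFrame:
    """One row per contrast: n, mean diff, SD, limits of agreement, t, p."""
    rows = []
    for contrast, sample in contrasts_from_response_table(table).items():
        r = bland_altman(sample)
        rows.append(
            {
                "contrast": contrast.value,
                "n": r.n,
                "mean_difference": r.mean_difference,
                "sd_difference": r.sd_difference,
                "loa_low": r.loa_low,
                "loa_high": r.loa_high,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def write_agreement_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)


def plot_bland_altman(sample: PairedSample, path) -> None:
    """Convenience Bland-Altman plot: mean on x, difference on y."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = bland_altman(sample)
    d = sample.differences
    m = (np.asarray(sample.first) + np.asarray(sample.second)) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=18)
    for y, ls in ((r.mean_difference, "-"), (r.loa_low, ":"), (r.loa_high, ":")):
        ax.axhline(y, ls=ls, color="k", lw=1)
    ax.set_xlabel("mean of paired change rates (%)")
    ax.set_ylabel("difference (%)")
    ax.set_title(sample.contrast.value)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
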