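"""Outlier-nodule detection: growth beyond 1.5x linear scale between scans.

A nodule is an outlier on a metric when its change ratio strictly exceeds
the criterion for that metric: 0.5 for the 3D maximum diameter (1.5x linear
growth) and 2.375 = 1.5**3 - 1 for the volume (the same linear growth
propagated through the cube law).  Only growth flags; shrinkage never does.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import Metric, PatientSeries, change_records

__all__ = [
    "DIAMETER_CRITERION",
    "VOLUME_CRITERION",
    "OutlierReport",
    "outlier_criterion",
    "detect_outliers",
    "outlier_frame",
    "write_outlier_report",
]

DIAMETER_CRITERION = 0.5
VOLUME_CRITERION = 1.5**3 - 1.0  # 2.375 exactly


@dataclass(frozen=True)
class OutlierReport:
    patient_id: str
    metric: Metric
    criterion: float
    outlier_nodule_ids: tuple[str, ...]


def outlier_criterion(metric: Metric) -> float:
    """Change-ratio criterion: 0.5 (diameter) or 1.5**3 - 1 = 2.375 (volume)."""
    metric = Metric(metric)
    if metric is Metric.DIAMETER:
        return DIAMETER_CRITERION
    return VOLUME_CRITERION


def detect_outliers(series: PatientSeries, metric: Metric) -> OutlierReport:
    """Flag every nodule whose change ratio strictly exceeds the criterion.

    Exactly-1.5x growth (ratio == criterion) does not flag; order of nodules
    in the series does not affect the flag set.
    """
    metric = Metric(metric)
    crit = outlier_criterion(metric)
    flagged = tuple(
        rec.nodule_id
        for rec in change_records(series, metric)
        if rec.ratio > crit
    )
    return OutlierReport(
        patient_id=series.patient_id,
        metric=metric,
        criterion=crit,
        outlier_nodule_ids=flagged,
    )


def outlier_frame(cohort: list[PatientSeries]) -> pd.DataFrame:
    """Per-patient outlier summary for both metrics."""
    rows = []
    for s in cohort:
        row: dict = {"patient_id": s.patient_id, "n_nodules": s.n_nodules}
        for metric, prefix in ((Metric.DIAMETER, "diam"), (Metric.VOLUME, "vol")):
            rep = detect_outliers(s, metric)
            row[f"{prefix}_criterion"] = rep.criterion
            row[f"{prefix}_n_outliers"] = len(rep.outlier_nodule_ids)
            row[f"{prefix}_outlier_ids"] = ";".join(rep.outlier_nodule_ids)
        rows.append(row)
    return pd.DataFrame(rows)


def write_outlier_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)


def plot_change_ratios(cohort: list[PatientSeries], metric: Metric, path) -> None:
    """Convenience scatter of per-nodule change ratios with the criterion line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metric = Metric(metric)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, s in enumerate(cohort):
        ratios = [r.ratio for r in change_records(s, metric)]
        ax.scatter([i + 1] * len(ratios), ratios, s=12, alpha=0.7)
    ax.axhline(outlier_criterion(metric), ls=":", color="k")
    ax.set_xlabel("patient")
    ax.set_ylabel(f"{metric.value} change ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
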