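"""RECIST 1.1 response categorization from change rates of target-lesion sums.

Categories follow the standard four-level scheme — complete response (CR),
partial response (PR), stable disease (SD), progressive disease (PD) — with
the linear thresholds of RECIST 1.1 (PD: more than +20% in the diameter sum,
PR: more than -30%) and the volumetric equivalents obtained by cubing the
linear factors (PD: more than +73%, PR: more than -66%).  Thresholds are
exclusive: a change of exactly +20% (or -30%, +73%, -66%) is SD.  The change
rate is always computed on the *sums* of the selected target lesions, never
as a mean of per-nodule rates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .core import (
    InvalidMeasurementError,
    Metric,
    PatientSeries,
    SelectionMode,
    Visit,
    change_rate,
    select_targets,
    sum_metric,
)

__all__ = [
    "Category",
    "ResponseAssessment",
    "DIAMETER_PD_PERCENT",
    "DIAMETER_PR_PERCENT",
    "VOLUME_PD_PERCENT",
    "VOLUME_PR_PERCENT",
    "classify_diameter",
    "classify_volume",
    "classify",
    "assess",
    "assess_cohort",
    "write_response_report",
]

DIAMETER_PD_PERCENT = 20.0
DIAMETER_PR_PERCENT = -30.0
VOLUME_PD_PERCENT = 73.0
VOLUME_PR_PERCENT = -66.0


class Category(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


@dataclass(frozen=True)
class ResponseAssessment:
    """One patient's response on one metric under one selection mode."""

    patient_id: str
    metric: Metric
    mode: SelectionMode
    sum_v1: float
    sum_v2: float
    change_percent: float
    category: Category


def _classify(
    change_percent: float,
    all_disappeared: bool,
    pd_threshold: float,
    pr_threshold: float,
) -> Category:
    if not change_percent >= -100.0:
        raise InvalidMeasurementError(
            f"change rate below -100% is impossible for non-negative "
            f"measurements: {change_percent!r}"
        )
    if all_disappeared:
        return Category.CR
    if change_percent > pd_threshold:
        return Category.PD
    if change_percent < pr_threshold:
        return Category.PR
    return Category.SD


def classify_diameter(change_percent: float, all_disappeared: bool = False) -> Category:
    """Linear RECIST category: PD above +20%, PR below -30%, boundaries SD."""
    return _classify(change_percent, all_disappeared, DIAMETER_PD_PERCENT, DIAMETER_PR_PERCENT)


def classify_volume(change_percent: float, all_disappeared: bool = False) -> Category:
    """Volumetric category: PD above +73%, PR below -66%, boundaries SD."""
    return _classify(change_percent, all_disappeared, VOLUME_PD_PERCENT, VOLUME_PR_PERCENT)


def classify(metric: Metric, change_percent: float, all_disappeared: bool = False) -> Category:
    if Metric(metric) is Metric.DIAMETER:
        return classify_diameter(change_percent, all_disappeared)
    return classify_volume(change_percent, all_disappeared)


def assess(
    series: PatientSeries,
    metric: Metric,
    mode: SelectionMode,
    *,
    select_by: Metric | None = None,
) -> ResponseAssessment:
    """Assess one patient: select targets, sum the metric at both visits,
    compute the change rate of the sums, and classify."""
    metric, mode = Metric(metric), SelectionMode(mode)
    targets = select_targets(series, metric, mode, select_by=select_by)
    s1 = sum_metric(targets, metric, Visit.V1)
    s2 = sum_metric(targets, metric, Visit.V2)
    change = change_rate(s1, s2)
    all_gone = all(t.value(metric, Visit.V2) == 0 for t in targets)
    return ResponseAssessment(
        patient_id=series.patient_id,
        metric=metric,
        mode=mode,
        sum_v1=s1,
        sum_v2=s2,
        change_percent=change,
        category=classify(metric, change, all_gone),
    )


def assess_cohort(
    cohort: list[PatientSeries],
    *,
    select_by: Metric | None = None,
) -> pd.DataFrame:
    """Both metrics x both modes for every patient, as a tidy frame shaped
    like the study's volumetry response table (one row per patient x mode)."""
    rows = []
    for s in cohort:
        for mode in (SelectionMode.TWO_LARGEST, SelectionMode.ALL):
            row: dict = {
                "patient_id": s.patient_id,
                "n_nodules": s.n_nodules,
                "mode": mode.value,
            }
            for metric, prefix, unit in (
                (Metric.DIAMETER, "diam", "cm"),
                (Metric.VOLUME, "vol", "cm3"),
            ):
                a = assess(s, metric, mode, select_by=select_by)
                row[f"{prefix}_sum1_{unit}"] = a.sum_v1
                row[f"{prefix}_sum2_{unit}"] = a.sum_v2
                row[f"{prefix}_change_percent"] = a.change_percent
                row[f"{prefix}_response"] = a.category.value
            rows.append(row)
    return pd.DataFrame(rows)


def write_response_report(report: pd.DataFrame, path) -> None:
    """Write the cohort assessment with change rates rounded to 1 decimal,
    matching the precision the study tables report."""
    out = report.copy()
    for col in out.columns:
        if col.endswith("_change_percent"):
            out[col] = out[col].round(1)
    out.to_csv(path, index=False)
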