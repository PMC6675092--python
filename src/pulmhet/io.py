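"""Reading and writing the shared measurement-table format, plus study fixtures.

The pipeline's single input format is a comma-separated table with a header
row and one row per nodule:

    patient_id,nodule_id,diameter_v1_cm,diameter_v2_cm,volume_v1_cm3,volume_v2_cm3,interval_days

``interval_days`` is patient-level metadata repeated on every row of that
patient; rows disagreeing on it are rejected.

The packaged fixtures are the study's printed summary tables: per-patient
manual two-diameter sums (10 patients), per-patient 3D-volumetry sums for
both metrics under both target-selection modes, and the per-patient
minimum p-values with heterogeneity verdicts.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    InvalidMeasurementError,
    NoduleMeasurement,
    PatientSeries,
)

MEASUREMENT_COLUMNS = [
    "patient_id",
    "nodule_id",
    "diameter_v1_cm",
    "diameter_v2_cm",
    "volume_v1_cm3",
    "volume_v2_cm3",
    "interval_days",
]

__all__ = [
    "MEASUREMENT_COLUMNS",
    "MalformedTableError",
    "read_measurement_table",
    "series_from_frame",
    "series_to_frame",
    "write_measurement_table",
    "load_manual_assessment_table",
    "load_volumetry_assessment_table",
    "load_heterogeneity_table",
]


class MalformedTableError(ValueError):
    """Input table failed validation; ``.problems`` lists row-level messages."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid measurement table:\n" + "\n".join(self.problems)
        )


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("pulmhet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_manual_assessment_table() -> pd.DataFrame:
    """Per-patient manual caliper measurements: two-diameter sums at both
    visits, percent change and response category, for the 10-patient cohort."""
    return _fixture("table1.csv")


def load_volumetry_assessment_table() -> pd.DataFrame:
    """Per-patient 3D-volumetry sums (diameter cm / volume cm^3) under both
    target-selection modes, with printed change rates and categories."""
    return _fixture("table2.csv")


def load_heterogeneity_table() -> pd.DataFrame:
    """Per-patient minimum combination-test p-values and overall verdicts."""
    df = _fixture("table3.csv")
    df["heterogeneous"] = df["heterogeneous"].map({"Yes": True, "No": False})
    return df


def series_from_frame(df: pd.DataFrame) -> list[PatientSeries]:
    """Build validated :class:`PatientSeries` objects from a measurement frame.

    Raises :class:`MalformedTableError` listing every offending row (1-based
    data row numbers, excluding the header) rather than stopping at the first.
    """
    problems: list[str] = []
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedTableError([f"missing columns: {missing}"])
    if len(df) == 0:
        raise MalformedTableError(["table contains no data rows"])

    series: list[PatientSeries] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        intervals = set(grp["interval_days"].tolist())
        if len(intervals) > 1:
            problems.append(
                f"patient {pid}: inconsistent interval_days values {sorted(intervals)}"
            )
            continue
        nodules = []
        ok = True
        for idx, row in grp.iterrows():
            rowno = int(idx) + 1
            try:
                nodules.append(
                    NoduleMeasurement(
                        nodule_id=str(row["nodule_id"]),
                        diameter_v1=float(row["diameter_v1_cm"]),
                        diameter_v2=float(row["diameter_v2_cm"]),
                        volume_v1=float(row["volume_v1_cm3"]),
                        volume_v2=float(row["volume_v2_cm3"]),
                    )
                )
            except (InvalidMeasurementError, TypeError, ValueError) as exc:
                problems.append(f"row {rowno} (patient {pid}): {exc}")
                ok = False
        if not ok:
            continue
        try:
            series.append(
                PatientSeries(
                    patient_id=str(pid),
                    interval_days=int(intervals.pop()),
                    nodules=tuple(nodules),
                )
            )
        except (InvalidMeasurementError, ValueError) as exc:
            problems.append(f"patient {pid}: {exc}")
    if problems:
        raise MalformedTableError(problems)
    return series


def read_measurement_table(path: str | Path) -> list[PatientSeries]:
    """Read and validate a per-nodule measurement CSV."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise MalformedTableError([f"{path}: file is empty"]) from None
    return series_from_frame(df)


def series_to_frame(series: Iterable[PatientSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for n in s.nodules:
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "nodule_id": n.nodule_id,
                    "diameter_v1_cm": n.diameter_v1,
                    "diameter_v2_cm": n.diameter_v2,
                    "volume_v1_cm3": n.volume_v1,
                    "volume_v2_cm3": n.volume_v2,
                    "interval_days": s.interval_days,
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurement_table(series: Iterable[PatientSeries], path: str | Path) -> None:
    # %.17g guarantees floats survive the text round trip bit-exactly
    series_to_frame(series).to_csv(path, index=False, float_format="%.17g")
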