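"""Domain types and elementary change metrics for longitudinal nodule measurements.

Every downstream stage (response assessment, outlier detection, the
minimum-combination heterogeneity test, agreement analysis) consumes the
types defined here: a :class:`NoduleMeasurement` holds one nodule's 3D
maximum diameter (cm) and volume (cm**3) at two CT visits, a
:class:`PatientSeries` groups a patient's nodules with the inter-scan
interval, and :class:`ChangeRecord` carries the per-nodule change rate

    rate (%) = 100 * (visit2 - visit1) / visit1

with positive = growth, negative = shrinkage, zero = no change.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Metric",
    "SelectionMode",
    "Visit",
    "NoduleMeasurement",
    "PatientSeries",
    "ChangeRecord",
    "InvalidMeasurementError",
    "InsufficientLesionsError",
    "change_rate",
    "change_ratio",
    "change_records",
    "select_targets",
    "sum_metric",
]


class InvalidMeasurementError(ValueError):
    """A measurement violates its domain (e.g. non-positive baseline)."""


class InsufficientLesionsError(ValueError):
    """An operation needs more lesions than the patient has."""


class Metric(str, enum.Enum):
    """Which CT-derived size parameter a computation operates on."""

    DIAMETER = "diameter"
    VOLUME = "volume"


class SelectionMode(str, enum.Enum):
    """Target-lesion selection: the two largest nodules, or all of them."""

    TWO_LARGEST = "two_largest"
    ALL = "all"


class Visit(str, enum.Enum):
    V1 = "v1"
    V2 = "v2"


@dataclass(frozen=True)
class NoduleMeasurement:
    """One nodule's diameter (cm) and volume (cm**3) at two visits.

    Baseline values must be strictly positive; follow-up values may be zero,
    which encodes lesion disappearance (a -100% change) and feeds the
    complete-response rule at the patient level.
    """

    nodule_id: str
    diameter_v1: float
    diameter_v2: float
    volume_v1: float
    volume_v2: float

    def __post_init__(self) -> None:
        for name in ("diameter_v1", "volume_v1"):
            if not getattr(self, name) > 0:
                raise InvalidMeasurementError(
                    f"nodule {self.nodule_id!r}: {name} must be > 0, "
                    f"got {getattr(self, name)!r}"
                )
        for name in ("diameter_v2", "volume_v2"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise InvalidMeasurementError(
                    f"nodule {self.nodule_id!r}: {name} must be >= 0, got {v!r}"
                )

    def value(self, metric: Metric, visit: Visit) -> float:
        return getattr(self, f"{Metric(metric).value}_{Visit(visit).value}")

    @property
    def disappeared(self) -> bool:
        """True when both follow-up measurements are exactly zero."""
        return self.diameter_v2 == 0 and self.volume_v2 == 0


@dataclass(frozen=True)
class PatientSeries:
    """A patient's nodule set plus the interval (days) between the two CTs."""

    patient_id: str
    interval_days: int
    nodules: tuple[NoduleMeasurement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodules", tuple(self.nodules))
        if len(self.nodules) < 2:
            raise InsufficientLesionsError(
                f"patient {self.patient_id!r}: at least 2 nodules required, "
                f"got {len(self.nodules)}"
            )
        if not (int(self.interval_days) == self.interval_days and self.interval_days > 0):
            raise InvalidMeasurementError(
                f"patient {self.patient_id!r}: interval_days must be a positive "
                f"integer, got {self.interval_days!r}"
            )
        ids = [n.nodule_id for n in self.nodules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidMeasurementError(
                f"patient {self.patient_id!r}: duplicate nodule ids {dupes}"
            )

    @property
    def n_nodules(self) -> int:
        return len(self.nodules)


@dataclass(frozen=True)
class ChangeRecord:
    """A single nodule's change on one metric, as percent and as a fraction."""

    nodule_id: str
    metric: Metric
    rate_percent: float
    disappeared: bool = field(default=False)

    @property
    def ratio(self) -> float:
        """Change as a signed decimal fraction (rate_percent / 100)."""
        return self.rate_percent / 100.0


def change_rate(v1: float, v2: float) -> float:
    """Percent change 100*(v2 - v1)/v1 between two visits.

    Parameters
    ----------
    v1 : baseline measurement, must be strictly positive.
    v2 : follow-up measurement, must be non-negative (0 = disappearance,
         giving -100%).
    """
    if not v1 > 0:
        raise InvalidMeasurementError(f"baseline must be > 0, got {v1!r}")
    if not v2 >= 0:
        raise InvalidMeasurementError(f"follow-up must be >= 0, got {v2!r}")
    return 100.0 * (v2 - v1) / v1


def change_ratio(v1: float, v2: float) -> float:
    """Change as a decimal fraction: (v2 - v1)/v1."""
    return change_rate(v1, v2) / 100.0


def change_records(series: PatientSeries, metric: Metric) -> tuple[ChangeRecord, ...]:
    """Per-nodule change rates on one metric, one record per nodule in order."""
    metric = Metric(metric)
    out = []
    for nod in series.nodules:
        rate = change_rate(nod.value(metric, Visit.V1), nod.value(metric, Visit.V2))
        out.append(
            ChangeRecord(
                nodule_id=nod.nodule_id,
                metric=metric,
                rate_percent=rate,
                disappeared=nod.value(metric, Visit.V2) == 0,
            )
        )
    return tuple(out)


def select_targets(
    series: PatientSeries,
    metric: Metric,
    mode: SelectionMode,
    *,
    select_by: Metric | None = None,
) -> tuple[NoduleMeasurement, ...]:
    """Target-lesion subset: the two with largest baseline value, or all.

    ``select_by`` controls which metric ranks the nodules (default: the
    metric under assessment).  Ties are broken by ascending ``nodule_id``
    so selection is deterministic.
    """
    metric = Metric(metric)
    mode = SelectionMode(mode)
    if mode is SelectionMode.ALL:
        return series.nodules
    if series.n_nodules < 2:
        raise InsufficientLesionsError(
            f"patient {series.patient_id!r}: two-largest selection needs >= 2 nodules"
        )
    rank_by = Metric(select_by) if select_by is not None else metric
    ordered = sorted(
        series.nodules,
        key=lambda n: (-n.value(rank_by, Visit.V1), n.nodule_id),
    )
    return tuple(ordered[:2])


def sum_metric(
    targets: Sequence[NoduleMeasurement] | Iterable[NoduleMeasurement],
    metric: Metric,
    visit: Visit,
) -> float:
    """Arithmetic sum of the chosen metric over a non-empty target set."""
    targets = tuple(targets)
    if not targets:
        raise InsufficientLesionsError("empty target set")
    metric, visit = Metric(metric), Visit(visit)
    return float(sum(n.value(metric, visit) for n in targets))
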