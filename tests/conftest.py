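import math

import pytest

from pulmhet.core import NoduleMeasurement, PatientSeries
from pulmhet.io import (
    load_heterogeneity_table,
    load_manual_assessment_table,
    load_volumetry_assessment_table,
)


def cube_volume(d: float, k: float = math.pi / 6.0) -> float:
    return k * d**3


def make_series(
    diameter_pairs,
    patient_id: str = "p1",
    interval_days: int = 60,
    volume_pairs=None,
):
    """PatientSeries from (d1, d2) pairs; volumes follow the exact cube law
    unless explicit (v1, v2) pairs are given."""
    if volume_pairs is None:
        volume_pairs = [(cube_volume(a), cube_volume(b)) for a, b in diameter_pairs]
    nodules = tuple(
        NoduleMeasurement(
            nodule_id=f"n{i + 1:02d}",
            diameter_v1=d1,
            diameter_v2=d2,
            volume_v1=v1,
            volume_v2=v2,
        )
        for i, ((d1, d2), (v1, v2)) in enumerate(zip(diameter_pairs, volume_pairs))
    )
    return PatientSeries(patient_id=patient_id, interval_days=interval_days, nodules=nodules)


@pytest.fixture(scope="session")
def manual_table():
    return load_manual_assessment_table()


@pytest.fixture(scope="session")
def volumetry_table():
    return load_volumetry_assessment_table()


@pytest.fixture(scope="session")
def heterogeneity_table():
    return load_heterogeneity_table()
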