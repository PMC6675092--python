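import math

import pytest
from hypothesis import given, strategies as st

from pulmhet.core import (
    InsufficientLesionsError,
    InvalidMeasurementError,
    Metric,
    NoduleMeasurement,
    PatientSeries,
    SelectionMode,
    Visit,
    change_rate,
    change_ratio,
    change_records,
    select_targets,
    sum_metric,
)
from conftest import make_series

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestChangeRate:
    @pytest.mark.parametrize(
        "v1, v2, expected",
        [
            (4.1, 2.9, -29.3),   # the cohort's largest manual shrinkage
            (3.2, 2.1, -34.4),   # the single partial response
            (2.2, 2.2, 0.0),
            (1.0, 1.2, 20.0),
            (1.0, 0.0, -100.0),  # disappearance
        ],
    )
    def test_reported_values(self, v1, v2, expected):
        assert round(change_rate(v1, v2), 1) == expected

    @given(v=positive)
    def test_identity_is_zero(self, v):
        assert change_rate(v, v) == 0.0

    @given(v1=positive, v2=positive, c=positive)
    def test_scale_invariance(self, v1, v2, c):
        assert change_rate(c * v1, c * v2) == pytest.approx(change_rate(v1, v2), rel=1e-9)

    @given(d1=positive, d2=positive)
    def test_cube_law_links_diameter_and_volume_ratios(self, d1, d2):
        r = change_ratio(d1, d2)
        rv = change_ratio(d1**3, d2**3)
        assert rv == pytest.approx((1 + r) ** 3 - 1, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("v1", [0.0, -1.0])
    def test_nonpositive_baseline_rejected(self, v1):
        with pytest.raises(InvalidMeasurementError):
            change_rate(v1, 1.0)


class TestDomainTypes:
    def test_nodule_requires_positive_baselines(self):
        with pytest.raises(InvalidMeasurementError):
            NoduleMeasurement("a", diameter_v1=0.0, diameter_v2=1, volume_v1=1, volume_v2=1)
        with pytest.raises(InvalidMeasurementError):
            NoduleMeasurement("a", diameter_v1=1, diameter_v2=1, volume_v1=-0.1, volume_v2=1)

    def test_followup_zero_means_disappearance(self):
        n = NoduleMeasurement("a", 1.0, 0.0, 0.5, 0.0)
        assert n.disappeared

    def test_series_rejects_duplicate_ids_and_short_series(self):
        n = NoduleMeasurement("a", 1, 1, 1, 1)
        with pytest.raises(InvalidMeasurementError):
            PatientSeries("p", 30, (n, n))
        with pytest.raises(InsufficientLesionsError):
            PatientSeries("p", 30, (n,))
        with pytest.raises(InvalidMeasurementError):
            PatientSeries("p", 0, (n, NoduleMeasurement("b", 1, 1, 1, 1)))


class TestChangeRecords:
    def test_one_record_per_nodule_in_order(self):
        s = make_series([(1.0, 1.0), (2.0, 2.2), (1.5, 1.2), (0.8, 1.6)])
        recs = change_records(s, Metric.DIAMETER)
        assert [r.nodule_id for r in recs] == [n.nodule_id for n in s.nodules]
        assert recs[0].rate_percent == 0.0
        assert recs[3].ratio == pytest.approx(1.0)  # doubled diameter

    def test_rate_percent_is_100x_ratio(self):
        s = make_series([(1.0, 1.3), (2.0, 1.0)])
        for r in change_records(s, Metric.VOLUME):
            assert r.rate_percent == pytest.approx(100 * r.ratio)


class TestTargetSelection:
    def test_two_largest_by_baseline(self):
        s = make_series([(1.0, 1.0), (2.0, 2.0), (1.5, 1.5)])
        picked = select_targets(s, Metric.DIAMETER, SelectionMode.TWO_LARGEST)
        assert [n.diameter_v1 for n in picked] == [2.0, 1.5]

    def test_exactly_two_nodules_either_mode(self):
        s = make_series([(1.0, 1.0), (2.0, 2.0)])
        for mode in SelectionMode:
            assert len(select_targets(s, Metric.DIAMETER, mode)) == 2

    def test_ties_broken_by_ascending_nodule_id(self):
        s = make_series([(2.0, 1.0), (2.0, 2.0), (2.0, 3.0)])
        picked = select_targets(s, Metric.DIAMETER, SelectionMode.TWO_LARGEST)
        assert [n.nodule_id for n in picked] == ["n01", "n02"]

    def test_select_by_diameter_overrides_metric(self):
        # largest volume is n01, largest diameter n02
        s = make_series(
            [(1.0, 1.0), (2.0, 2.0)],
            volume_pairs=[(9.0, 9.0), (1.0, 1.0)],
        )
        same = select_targets(s, Metric.VOLUME, SelectionMode.TWO_LARGEST)
        by_d = select_targets(s, Metric.VOLUME, SelectionMode.TWO_LARGEST,
                              select_by=Metric.DIAMETER)
        assert same[0].nodule_id == "n01" and by_d[0].nodule_id == "n02"


class TestSumMetric:
    def test_sum_matches_manual_addition(self):
        s = make_series([(1.1, 1.0), (2.2, 2.0), (0.7, 0.9)])
        assert sum_metric(s.nodules, Metric.DIAMETER, Visit.V1) == pytest.approx(4.0)
        assert sum_metric(s.nodules, Metric.DIAMETER, Visit.V2) == pytest.approx(3.9)

    def test_single_nodule_sum_is_its_value(self):
        s = make_series([(1.3, 1.1), (0.4, 0.4)])
        assert sum_metric(s.nodules[:1], Metric.VOLUME, Visit.V1) == s.nodules[0].volume_v1

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientLesionsError):
            sum_metric((), Metric.DIAMETER, Visit.V1)
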