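"""Cohort logic: indication rule, exclusions, quarterly aggregation."""

import random
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scanspc import (
    IndicationClass,
    PatientRecord,
    aggregate_quarterly,
    apply_exclusions,
    classify_bone_scan_indication,
    read_registry_csv,
    write_registry_csv,
)
from scanspc.cohort import quarter_label


def record(**overrides):
    base = dict(
        patient_id="p1",
        practice_id="A",
        diagnosis_date=date(2014, 2, 10),
        first_encounter_date=date(2014, 2, 12),
        gleason_total=6,
        psa_ng_ml=5.0,
        bone_scan_performed="no",
        bone_scan_order_source="none",
        no_imaging_recorded_date=date(2014, 5, 1),
    )
    base.update(overrides)
    return PatientRecord(**base)


# ---------------------------------------------------------------------------
# indication classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "gleason,psa,expected",
    [
        (6, 4.5, IndicationClass.NOT_INDICATED),
        (7, 19.9, IndicationClass.NOT_INDICATED),
        (7, 20.0, IndicationClass.NOT_INDICATED),  # PSA boundary is inclusive
        (7, 20.01, IndicationClass.INDICATED),
        (8, 4.5, IndicationClass.INDICATED),  # Gleason boundary is exclusive
        (10, 150.0, IndicationClass.INDICATED),
        (2, 0.0, IndicationClass.NOT_INDICATED),
        (None, 4.5, IndicationClass.UNCLASSIFIABLE),
        (6, None, IndicationClass.UNCLASSIFIABLE),
        (None, None, IndicationClass.UNCLASSIFIABLE),
    ],
)
def test_indication_rule(gleason, psa, expected):
    assert classify_bone_scan_indication(gleason, psa) is expected


@pytest.mark.parametrize("gleason,psa", [(1, 5.0), (11, 5.0), (6, -0.1)])
def test_indication_rule_domain_errors(gleason, psa):
    with pytest.raises(ValueError):
        classify_bone_scan_indication(gleason, psa)


def test_classification_is_per_record():
    records = [record(patient_id=str(i), gleason_total=g) for i, g in enumerate([6, 8, 7])]
    classes = [r.indication for r in records]
    random.Random(0).shuffle(records)
    assert sorted(c.value for c in classes) == sorted(r.indication.value for r in records)


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------


def test_missing_imaging_status_excluded():
    retained, tally = apply_exclusions([record(bone_scan_performed="missing")])
    assert retained == []
    assert tally.missing_imaging_status == 1


def test_early_no_imaging_record_excluded_strictly_before_day_30():
    entry = date(2014, 2, 10)
    early = record(no_imaging_recorded_date=entry + timedelta(days=10))
    boundary = record(no_imaging_recorded_date=entry + timedelta(days=30))
    retained, tally = apply_exclusions([early, boundary])
    assert tally.early_no_imaging_record == 1
    assert len(retained) == 1 and retained[0].no_imaging_recorded_date == entry + timedelta(days=30)


def test_entry_date_is_earlier_of_the_two_dates():
    # encounter precedes diagnosis; window anchors on the encounter
    rec = record(
        diagnosis_date=date(2014, 3, 1),
        first_encounter_date=date(2014, 2, 1),
        no_imaging_recorded_date=date(2014, 2, 25),
    )
    _, tally = apply_exclusions([rec])
    assert tally.early_no_imaging_record == 1


def test_external_scan_only_excluded():
    rec = record(bone_scan_performed="yes", bone_scan_order_source="external")
    retained, tally = apply_exclusions([rec])
    assert retained == [] and tally.external_scan_only == 1


def test_unclassifiable_excluded_and_tallied():
    rec = record(gleason_total=None)
    retained, tally = apply_exclusions([rec])
    assert retained == [] and tally.unclassifiable == 1


def test_scanned_patient_retained():
    rec = record(bone_scan_performed="yes", bone_scan_order_source="internal",
                 no_imaging_recorded_date=None)
    retained, tally = apply_exclusions([rec])
    assert len(retained) == 1 and tally.retained == 1


@given(
    st.lists(
        st.builds(
            record,
            bone_scan_performed=st.sampled_from(["yes", "no", "missing"]),
            bone_scan_order_source=st.sampled_from(["internal", "external", "none"]),
            gleason_total=st.one_of(st.none(), st.integers(2, 10)),
            psa_ng_ml=st.one_of(st.none(), st.floats(0, 100)),
            no_imaging_recorded_date=st.one_of(
                st.none(),
                st.dates(date(2014, 2, 10), date(2014, 8, 1)),
            ),
        ),
        max_size=40,
    )
)
@settings(max_examples=60, deadline=None)
def test_exclusion_tally_conservation(records):
    retained, tally = apply_exclusions(records)
    assert tally.retained == len(retained)
    assert tally.retained + tally.total_excluded == len(records)
    # order independence
    shuffled = list(records)
    random.Random(1).shuffle(shuffled)
    _, tally2 = apply_exclusions(shuffled)
    assert tally.as_dict() == tally2.as_dict()


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_single_quarter_aggregation():
    records = [
        record(patient_id=str(i), bone_scan_performed="no",
               no_imaging_recorded_date=date(2014, 6, 1))
        for i in range(26)
    ]
    series = aggregate_quarterly(records)
    (s,) = series.values()
    assert len(s) == 1
    assert s.n[0] == 26 and s.x[0] == 0
    assert s.rates[0] == 0.0


def test_aggregation_emits_and_flags_empty_quarters():
    a = record(patient_id="a", diagnosis_date=date(2014, 1, 5),
               first_encounter_date=date(2014, 1, 6))
    b = record(patient_id="b", diagnosis_date=date(2014, 9, 5),
               first_encounter_date=date(2014, 9, 6),
               no_imaging_recorded_date=date(2014, 12, 1))
    series = aggregate_quarterly([a, b])
    (s,) = series.values()
    assert s.n.tolist() == [1, 0, 1]
    assert s.quarter_labels == ["2014Q1", "2014Q2", "2014Q3"]


def test_aggregation_filters_by_indication_class():
    not_ind = record(patient_id="a")
    ind = record(patient_id="b", gleason_total=9, bone_scan_performed="yes",
                 bone_scan_order_source="internal", no_imaging_recorded_date=None)
    series = aggregate_quarterly([not_ind, ind], IndicationClass.NOT_INDICATED)
    (s,) = series.values()
    assert s.n.sum() == 1 and s.x.sum() == 0
    series_ind = aggregate_quarterly([not_ind, ind], IndicationClass.INDICATED)
    (s2,) = series_ind.values()
    assert s2.n.sum() == 1 and s2.x.sum() == 1


def test_quarter_convention_switch():
    rec = record(diagnosis_date=date(2014, 3, 30), first_encounter_date=date(2014, 4, 2))
    by_entry = aggregate_quarterly([rec], quarter_by="entry")
    by_enc = aggregate_quarterly([rec], quarter_by="encounter")
    assert list(by_entry.values())[0].quarter_labels == ["2014Q1"]
    assert list(by_enc.values())[0].quarter_labels == ["2014Q2"]


def test_empty_input_gives_empty_series():
    assert aggregate_quarterly([]) == {}


def test_quarter_label():
    assert quarter_label(date(2014, 8, 1)) == "2014Q3"
    assert quarter_label(date(2014, 1, 31)) == "2014Q1"


def test_pooled_rates_on_crafted_counts():
    """A cohort built to known counts reproduces its pooled rates exactly."""
    records = []
    for i in range(200):  # 200 non-indicated, 15 scanned: 7.5%
        scanned = i < 15
        records.append(
            record(
                patient_id=f"n{i}",
                bone_scan_performed="yes" if scanned else "no",
                bone_scan_order_source="internal" if scanned else "none",
                no_imaging_recorded_date=None if scanned else date(2014, 6, 1),
            )
        )
    retained, tally = apply_exclusions(records)
    assert tally.retained == 200
    (s,) = aggregate_quarterly(retained).values()
    assert s.x.sum() / s.n.sum() == pytest.approx(0.075)


# ---------------------------------------------------------------------------
# registry CSV
# ---------------------------------------------------------------------------


def test_registry_csv_round_trip(tmp_path):
    records = [
        record(),
        record(patient_id="p2", gleason_total=None, psa_ng_ml=None,
               bone_scan_performed="missing", no_imaging_recorded_date=None),
        record(patient_id="p3", bone_scan_performed="yes",
               bone_scan_order_source="external", no_imaging_recorded_date=None),
    ]
    path = tmp_path / "registry.csv"
    write_registry_csv(records, path)
    back = read_registry_csv(path)
    assert back == records


def test_registry_csv_missing_columns_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("patient_id,practice_id\np1,A\n")
    with pytest.raises(ValueError):
        read_registry_csv(path)
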