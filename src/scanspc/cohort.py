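"""Cohort construction: bone-scan indication, exclusions, quarterly aggregation.

Staging bone scans are not indicated for newly diagnosed prostate-cancer
patients with Gleason score < 8 **and** PSA ≤ 20 ng/mL; a scan in that group
is the adherence failure the charts monitor.  This module classifies
indication, applies the registry exclusion rules, and rolls retained
patients up into per-practice quarterly count series.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .charts import QuarterlySeries

__all__ = [
    "PatientRecord",
    "IndicationClass",
    "ExclusionTally",
    "classify_bone_scan_indication",
    "apply_exclusions",
    "aggregate_quarterly",
    "quarter_label",
    "read_registry_csv",
    "write_registry_csv",
    "REGISTRY_COLUMNS",
]

REGISTRY_COLUMNS = [
    "patient_id",
    "practice_id",
    "diagnosis_date",
    "first_encounter_date",
    "gleason_total",
    "psa_ng_ml",
    "bone_scan_performed",
    "bone_scan_order_source",
    "no_imaging_recorded_date",
]


class IndicationClass(enum.Enum):
    """Bone-scan indication status under the imaging appropriateness rule."""

    NOT_INDICATED = "not_indicated"
    INDICATED = "indicated"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass
class PatientRecord:
    """One registry row: the clinical fields the cohort logic consumes.

    ``bone_scan_performed`` is tristate (``"yes"``/``"no"``/``"missing"``);
    ``bone_scan_order_source`` is ``"internal"`` (ordered within the
    collaborative), ``"external"``, or ``"none"``.  Either the diagnosis
    date or the first-encounter date may be absent; cohort entry is the
    earlier of whichever exist.
    """

    patient_id: str
    practice_id: str
    diagnosis_date: Optional[date] = None
    first_encounter_date: Optional[date] = None
    gleason_total: Optional[int] = None
    psa_ng_ml: Optional[float] = None
    bone_scan_performed: str = "missing"
    bone_scan_order_source: str = "none"
    no_imaging_recorded_date: Optional[date] = None

    @property
    def entry_date(self) -> Optional[date]:
        dates = [d for d in (self.diagnosis_date, self.first_encounter_date) if d is not None]
        return min(dates) if dates else None

    @property
    def indication(self) -> IndicationClass:
        return classify_bone_scan_indication(self.gleason_total, self.psa_ng_ml)


def classify_bone_scan_indication(
    gleason_total: Optional[int],
    psa_ng_ml: Optional[float],
) -> IndicationClass:
    """Classify bone-scan indication from Gleason score and PSA.

    Not indicated iff Gleason < 8 and PSA ≤ 20 ng/mL; indicated iff
    Gleason ≥ 8 or PSA > 20; unclassifiable when either field is missing.
    Both boundaries are sharp: (8, ·) and (·, 20.01) are indicated while
    (7, 20.0) is not.
    """
    if gleason_total is None or psa_ng_ml is None:
        return IndicationClass.UNCLASSIFIABLE
    gleason = int(gleason_total)
    psa = float(psa_ng_ml)
    if not 2 <= gleason <= 10:
        raise ValueError(f"Gleason total must lie in [2, 10]; got {gleason}")
    if psa < 0:
        raise ValueError(f"PSA must be non-negative; got {psa}")
    if gleason < 8 and psa <= 20.0:
        return IndicationClass.NOT_INDICATED
    return IndicationClass.INDICATED


@dataclass
class ExclusionTally:
    """Counts per exclusion reason plus the retained total.

    Conservation holds by construction: ``retained + total_excluded``
    equals the number of input records.
    """

    missing_imaging_status: int = 0
    early_no_imaging_record: int = 0
    external_scan_only: int = 0
    unclassifiable: int = 0
    retained: int = 0

    @property
    def total_excluded(self) -> int:
        return (
            self.missing_imaging_status
            + self.early_no_imaging_record
            + self.external_scan_only
            + self.unclassifiable
        )

    def as_dict(self) -> Dict[str, int]:
        return {
            "missing_imaging_status": self.missing_imaging_status,
            "early_no_imaging_record": self.early_no_imaging_record,
            "external_scan_only": self.external_scan_only,
            "unclassifiable": self.unclassifiable,
            "retained": self.retained,
        }


def apply_exclusions(
    records: Iterable[PatientRecord],
    window_days: int = 30,
) -> Tuple[List[PatientRecord], ExclusionTally]:
    """Apply the study exclusion rules; returns (retained records, tally).

    In precedence order, a record is excluded when

    1. imaging status is missing (or the row is malformed: no usable entry
       date, invalid Gleason/PSA) — ``missing_imaging_status``;
    2. lack of imaging was recorded strictly less than ``window_days`` days
       after cohort entry (day ``window_days`` itself is retained) —
       ``early_no_imaging_record``;
    3. the only bone-scan order came from outside the collaborative —
       ``external_scan_only``;
    4. the indication class cannot be determined — ``unclassifiable``.

    The tally is order-independent: each record is judged on its own.
    """
    retained: List[PatientRecord] = []
    tally = ExclusionTally()
    for rec in records:
        entry = rec.entry_date
        status = rec.bone_scan_performed
        try:
            indication = rec.indication
        except (ValueError, TypeError):
            tally.missing_imaging_status += 1
            continue
        if status not in ("yes", "no") or entry is None:
            tally.missing_imaging_status += 1
            continue
        if (
            status == "no"
            and rec.no_imaging_recorded_date is not None
            and rec.no_imaging_recorded_date < entry + timedelta(days=window_days)
        ):
            tally.early_no_imaging_record += 1
            continue
        if rec.bone_scan_order_source == "external":
            tally.external_scan_only += 1
            continue
        if indication is IndicationClass.UNCLASSIFIABLE:
            tally.unclassifiable += 1
            continue
        retained.append(rec)
        tally.retained += 1
    return retained, tally


def quarter_label(day: date) -> str:
    """Calendar-quarter label of a date, e.g. ``date(2014, 8, 1) -> '2014Q3'``."""
    return f"{day.year}Q{(day.month - 1) // 3 + 1}"


def _quarter_ordinal(day: date) -> int:
    return day.year * 4 + (day.month - 1) // 3


def _ordinal_label(q: int) -> str:
    return f"{q // 4}Q{q % 4 + 1}"


def aggregate_quarterly(
    records: Iterable[PatientRecord],
    class_filter: IndicationClass = IndicationClass.NOT_INDICATED,
    quarter_by: str = "entry",
) -> Dict[str, QuarterlySeries]:
    """Aggregate exclusion-filtered records into per-practice quarterly series.

    For each practice, ``n_t`` counts retained records in ``class_filter``
    entering in calendar quarter ``t`` and ``x_t`` counts those that
    received a bone scan.  Quarter indexing is shared across practices
    (starting at the earliest quarter in the data) so their series align;
    quarters without patients are emitted with ``n_t = 0`` and flagged by
    the charts.  ``quarter_by`` selects the anchoring date: ``"entry"``
    (earlier of the two dates; default), ``"diagnosis"`` or ``"encounter"``.
    """
    if quarter_by not in ("entry", "diagnosis", "encounter"):
        raise ValueError("quarter_by must be 'entry', 'diagnosis' or 'encounter'")

    def anchor(rec: PatientRecord) -> Optional[date]:
        if quarter_by == "diagnosis":
            return rec.diagnosis_date
        if quarter_by == "encounter":
            return rec.first_encounter_date
        return rec.entry_date

    buckets: Dict[str, Dict[int, List[PatientRecord]]] = {}
    all_quarters: List[int] = []
    for rec in records:
        if rec.indication is not class_filter:
            continue
        day = anchor(rec)
        if day is None:
            continue
        q = _quarter_ordinal(day)
        buckets.setdefault(rec.practice_id, {}).setdefault(q, []).append(rec)
        all_quarters.append(q)
    if not buckets:
        return {}
    q_lo, q_hi = min(all_quarters), max(all_quarters)
    span = range(q_lo, q_hi + 1)
    out: Dict[str, QuarterlySeries] = {}
    for practice, per_quarter in sorted(buckets.items()):
        n = np.array([len(per_quarter.get(q, [])) for q in span], dtype=np.int64)
        x = np.array(
            [
                sum(1 for r in per_quarter.get(q, []) if r.bone_scan_performed == "yes")
                for q in span
            ],
            dtype=np.int64,
        )
        out[practice] = QuarterlySeries(
            n=n,
            x=x,
            practice_id=practice,
            quarter_labels=[_ordinal_label(q) for q in span],
        )
    return out


# ---------------------------------------------------------------------------
# Registry CSV dialect
# ---------------------------------------------------------------------------


def _fmt_date(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def _parse_date(text: str) -> Optional[date]:
    text = text.strip()
    return date.fromisoformat(text) if text else None


def write_registry_csv(records: Iterable[PatientRecord], path) -> None:
    """Write records in the registry CSV dialect (header required)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(REGISTRY_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.practice_id,
                    _fmt_date(rec.diagnosis_date),
                    _fmt_date(rec.first_encounter_date),
                    "" if rec.gleason_total is None else rec.gleason_total,
                    "" if rec.psa_ng_ml is None else rec.psa_ng_ml,
                    {"yes": "true", "no": "false"}.get(rec.bone_scan_performed, "missing"),
                    rec.bone_scan_order_source,
                    _fmt_date(rec.no_imaging_recorded_date),
                ]
            )


def read_registry_csv(path) -> List[PatientRecord]:
    """Read a registry CSV; empty fields become missing values."""
    records: List[PatientRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        missing = set(REGISTRY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"registry CSV lacks required columns: {sorted(missing)}")
        for row in reader:
            performed = {"true": "yes", "false": "no"}.get(
                row["bone_scan_performed"].strip().lower(), "missing"
            )
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    practice_id=row["practice_id"],
                    diagnosis_date=_parse_date(row["diagnosis_date"]),
                    first_encounter_date=_parse_date(row["first_encounter_date"]),
                    gleason_total=int(row["gleason_total"]) if row["gleason_total"].strip() else None,
                    psa_ng_ml=float(row["psa_ng_ml"]) if row["psa_ng_ml"].strip() else None,
                    bone_scan_performed=performed,
                    bone_scan_order_source=row["bone_scan_order_source"].strip() or "none",
                    no_imaging_recorded_date=_parse_date(row["no_imaging_recorded_date"]),
                )
            )
    return records
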