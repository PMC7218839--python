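"""Synthetic registry and count-series generation.

The monitored process is a stream of Bernoulli adherence failures: each
bone-scan-non-indicated patient independently receives a non-indicated scan
with the active quarterly rate (5.9 % in control, 11.4 % out of control by
default), about 26 such patients arriving per practice-quarter.  This
module generates (a) quarterly count series with exactly that structure for
simulation work and (b) full patient-level registries whose covariates are
drawn conditionally on a pre-assigned indication class, so the cohort
module's classifier and exclusion filters reproduce the configured
composition exactly.

Randomness is organised as named child streams (volumes, classes, events,
covariates, dates, exclusions) spawned from one seed; per-patient event
draws are ordered by (quarter, patient index), so a quarterly count equals
the sum of its patients' Bernoulli outcomes and the two generation levels
agree in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .charts import QuarterlySeries
from .cohort import IndicationClass, PatientRecord

__all__ = [
    "SyntheticConfig",
    "generate_quarterly_series",
    "generate_registry",
    "inject_shift",
]

_STREAMS = ("volumes", "classes", "events", "covariates", "dates", "exclusions")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the study conditions.

    ``mean_volume`` is the per-quarter count of bone-scan-non-indicated
    patients per practice (26, the collaborative's mean volume);
    ``baseline_rate`` the in-control non-indicated scan rate (5.9 %);
    ``change_points`` a list of ``(quarter_index, new_rate)`` pairs taking
    effect from that quarter onward.  ``indicated_fraction`` (share of all
    patients for whom a scan IS indicated) and ``indicated_scan_rate`` are
    back-computed from the printed cohort composition, 4983/23 672 ≈ 0.21
    and 4044/4983 ≈ 0.811.  ``exclusion_rate`` > 0 injects records that
    trip the cohort exclusion filters, for testing; the default registry
    loses no records to exclusions.
    """

    n_practices: int = 1
    n_quarters: int = 20
    mean_volume: float = 26.0
    volume_model: str = "fixed"
    baseline_rate: float = 0.059
    change_points: Tuple[Tuple[int, float], ...] = ()
    indicated_fraction: float = 4983 / 23672
    indicated_scan_rate: float = 4044 / 4983
    seed: int = 0
    exclusion_rate: float = 0.0
    start_year: int = 2013

    def __post_init__(self) -> None:
        if self.n_practices < 1 or self.n_quarters < 1:
            raise ValueError("n_practices and n_quarters must be positive")
        if self.mean_volume <= 0:
            raise ValueError("mean_volume must be positive")
        if self.volume_model not in ("fixed", "poisson"):
            raise ValueError("volume_model must be 'fixed' or 'poisson'")
        for name in ("baseline_rate", "indicated_scan_rate", "exclusion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if not 0.0 <= self.indicated_fraction < 1.0:
            raise ValueError("indicated_fraction must lie in [0, 1)")
        object.__setattr__(self, "change_points", tuple(
            (int(q), float(r)) for q, r in self.change_points
        ))
        last = 0
        for q, r in self.change_points:
            if not 1 <= q <= self.n_quarters:
                raise ValueError(f"change point quarter {q} outside [1, {self.n_quarters}]")
            if q <= last:
                raise ValueError("change point quarters must be strictly increasing")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"change point rate {r} outside [0, 1]")
            last = q

    def rate_for_quarter(self, quarter: int) -> float:
        """Active non-indicated scan rate in 1-based ``quarter``."""
        rate = self.baseline_rate
        for q, r in self.change_points:
            if quarter >= q:
                rate = r
        return rate


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_quarterly_series(
    rate: float,
    n_per_quarter: int,
    n_quarters: int,
    seed: int = 0,
) -> QuarterlySeries:
    """Simulate a quarterly count series at a constant event rate.

    Per-patient Bernoulli(rate) outcomes are drawn in (quarter, patient)
    order and summed, so ``x_t ~ Binomial(n_per_quarter, rate)``
    independently across quarters and the attached patient stream is
    consistent with the counts.  Reproducible under a fixed seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1]; got {rate}")
    if n_per_quarter < 1 or n_quarters < 1:
        raise ValueError("n_per_quarter and n_quarters must be positive")
    rng = _streams(seed)["events"]
    events = (rng.random(size=(n_quarters, n_per_quarter)) < rate).astype(np.int64)
    periods = np.repeat(np.arange(1, n_quarters + 1), n_per_quarter)
    return QuarterlySeries(
        n=np.full(n_quarters, n_per_quarter, dtype=np.int64),
        x=events.sum(axis=1),
        stream_events=events.ravel(),
        stream_periods=periods,
    )


def inject_shift(
    series: QuarterlySeries,
    quarter: int,
    new_rate: float,
    seed: int = 0,
) -> QuarterlySeries:
    """Re-draw quarters from ``quarter`` onward at ``new_rate``.

    Periods before the change point are untouched (counts and patient
    stream alike); the tail is replaced by fresh Bernoulli draws.
    """
    if not 0.0 <= new_rate <= 1.0:
        raise ValueError(f"new_rate must lie in [0, 1]; got {new_rate}")
    if not 1 <= quarter <= len(series):
        raise IndexError(f"change-point quarter {quarter} outside [1, {len(series)}]")
    rng = _streams(seed)["events"]
    events, periods = series.as_stream(order="events_first")
    tail = periods >= quarter
    events = events.copy()
    events[tail] = (rng.random(tail.sum()) < new_rate).astype(np.int64)
    x = series.x.copy()
    for t in range(quarter, len(series) + 1):
        x[t - 1] = events[periods == t].sum()
    return QuarterlySeries(
        n=series.n.copy(),
        x=x,
        practice_id=series.practice_id,
        quarter_labels=series.quarter_labels,
        stream_events=events,
        stream_periods=periods,
    )


# ---------------------------------------------------------------------------
# Patient-level registry
# ---------------------------------------------------------------------------


def _quarter_start(config: SyntheticConfig, quarter: int) -> date:
    year = config.start_year + (quarter - 1) // 4
    month = 3 * ((quarter - 1) % 4) + 1
    return date(year, month, 1)


def _draw_covariates(
    rng: np.random.Generator, indicated: bool
) -> Tuple[int, float]:
    """Draw a (Gleason, PSA) pair consistent with the assigned class.

    Gleason from {6, ..., 10}, PSA log-normal; the pair is drawn
    conditionally on the class so the classifier reproduces it exactly.
    """
    if not indicated:
        gleason = int(rng.choice([6, 6, 7]))
        psa = float(np.exp(rng.normal(np.log(6.5), 0.5)))
        while psa > 20.0:
            psa = float(np.exp(rng.normal(np.log(6.5), 0.5)))
        return gleason, round(psa, 1)
    if rng.random() < 0.65:  # high-grade route
        gleason = int(rng.choice([8, 9, 10], p=[0.45, 0.45, 0.10]))
        psa = float(np.exp(rng.normal(np.log(12.0), 0.8)))
    else:  # high-PSA route
        gleason = int(rng.choice([6, 7]))
        psa = 20.0
        while psa <= 20.0:
            psa = float(np.exp(rng.normal(np.log(35.0), 0.6)))
    return gleason, round(psa, 1)


def _inject_exclusion(rec: PatientRecord, rng: np.random.Generator) -> PatientRecord:
    kind = rng.integers(3)
    if kind == 0:
        return replace(rec, bone_scan_performed="missing", bone_scan_order_source="none")
    if kind == 1:
        entry = rec.entry_date
        return replace(
            rec,
            bone_scan_performed="no",
            bone_scan_order_source="none",
            no_imaging_recorded_date=entry + timedelta(days=int(rng.integers(0, 30))),
        )
    return replace(rec, bone_scan_performed="yes", bone_scan_order_source="external")


def generate_registry(config: SyntheticConfig) -> List[PatientRecord]:
    """Generate a patient-level registry under ``config``.

    Per practice and quarter the generator draws the non-indicated and
    indicated patient volumes, assigns scan events at the quarter's active
    rate (non-indicated) or at ``indicated_scan_rate`` (indicated), and
    fills in covariates and dates so that, with ``exclusion_rate = 0``,
    every record passes the cohort exclusion filters.
    """
    rngs = _streams(config.seed)
    n_non_fixed = int(round(config.mean_volume))
    f = config.indicated_fraction
    mean_ind = config.mean_volume * f / (1.0 - f) if f > 0 else 0.0
    records: List[PatientRecord] = []
    for p in range(1, config.n_practices + 1):
        practice_id = f"P{p:02d}"
        for q in range(1, config.n_quarters + 1):
            if config.volume_model == "fixed":
                n_non = n_non_fixed
                n_ind = int(round(mean_ind))
            else:
                n_non = int(rngs["volumes"].poisson(config.mean_volume))
                n_ind = int(rngs["volumes"].poisson(mean_ind)) if mean_ind > 0 else 0
            rate = config.rate_for_quarter(q)
            q_start = _quarter_start(config, q)
            flags = [False] * n_non + [True] * n_ind
            for i, indicated in enumerate(flags):
                event_rate = config.indicated_scan_rate if indicated else rate
                scanned = bool(rngs["events"].random() < event_rate)
                gleason, psa = _draw_covariates(rngs["covariates"], indicated)
                diagnosis = q_start + timedelta(days=int(rngs["dates"].integers(0, 84)))
                encounter = diagnosis + timedelta(days=int(rngs["dates"].integers(0, 15)))
                rec = PatientRecord(
                    patient_id=f"{practice_id}-{q:03d}-{i + 1:03d}",
                    practice_id=practice_id,
                    diagnosis_date=diagnosis,
                    first_encounter_date=encounter,
                    gleason_total=gleason,
                    psa_ng_ml=psa,
                    bone_scan_performed="yes" if scanned else "no",
                    bone_scan_order_source="internal" if scanned else "none",
                    no_imaging_recorded_date=(
                        None
                        if scanned
                        else diagnosis + timedelta(days=30 + int(rngs["dates"].integers(0, 60)))
                    ),
                )
                if config.exclusion_rate > 0 and rngs["exclusions"].random() < config.exclusion_rate:
                    rec = _inject_exclusion(rec, rngs["exclusions"])
                records.append(rec)
    return records
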