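"""Attribute-data control charts for monitoring guideline-adherence rates.

Four chart families operate on a quarterly series of binomial counts
(``n_t`` eligible patients, ``x_t`` adherence failures, here non-indicated
bone scans):

* **p-chart** — plots the per-period proportion ``p̂_t = x_t/n_t`` against
  limits ``p0 ± L·sqrt(p0(1−p0)/n_t)``.
* **weighted binomial CUSUM** — accumulates per-period binomial
  log-likelihood-ratio increments designed for a shift ``p0 → p1``, with a
  zero floor, and alarms when the sum reaches a decision interval ``h``.
* **Bernoulli CUSUM** — the same accumulation updated patient-by-patient
  rather than per aggregated period.
* **EWMA** — an exponentially weighted moving average of the per-period
  proportions, compared to time-varying limits built from the exact
  variance recursion (which depends on each period's sample size).

All evaluators are pure functions of ``(series, parameters)``: no hidden
state, deterministic, order of calls irrelevant.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ChartFamily",
    "QuarterlySeries",
    "ChartSpec",
    "ChartResult",
    "cusum_weights",
    "pchart_evaluate",
    "wb_cusum_evaluate",
    "bernoulli_cusum_evaluate",
    "ewma_evaluate",
    "evaluate",
    "run_length",
]


class ChartFamily(str, enum.Enum):
    """The four attribute-data chart families compared by the package."""

    P_CHART = "p_chart"
    WB_CUSUM = "wb_cusum"
    BERNOULLI_CUSUM = "bernoulli_cusum"
    EWMA = "ewma"

    @classmethod
    def coerce(cls, value: Union[str, "ChartFamily"]) -> "ChartFamily":
        if isinstance(value, cls):
            return value
        return cls(str(value))


def _check_probability(name: str, value: float, open_interval: bool = False) -> float:
    value = float(value)
    if open_interval:
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must lie in (0, 1); got {value}")
    elif not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1]; got {value}")
    return value


# ---------------------------------------------------------------------------
# Series container
# ---------------------------------------------------------------------------


@dataclass
class QuarterlySeries:
    """Per-period counts for one monitored practice/cohort.

    Parameters
    ----------
    n
        Eligible patients per period (non-negative; a zero-volume period is
        kept but flagged and skipped by the charts).
    x
        Event counts (non-indicated scans) per period, ``0 <= x_t <= n_t``.
    practice_id
        Optional identifier of the monitored practice.
    quarter_labels
        Optional calendar labels such as ``"2014Q3"``, one per period.
    stream_events, stream_periods
        Optional per-patient binary outcomes with their 1-based period
        labels, ordered by (period, patient).  Required by the Bernoulli
        CUSUM; per-period sums must equal ``x``.
    """

    n: np.ndarray
    x: np.ndarray
    practice_id: Optional[str] = None
    quarter_labels: Optional[Sequence[str]] = None
    stream_events: Optional[np.ndarray] = None
    stream_periods: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        if self.n.ndim != 1 or self.x.shape != self.n.shape:
            raise ValueError("n and x must be 1-d arrays of equal length")
        if np.any(self.n < 0):
            raise ValueError("period sizes n_t must be non-negative")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            raise ValueError("counts must satisfy 0 <= x_t <= n_t")
        if self.quarter_labels is not None and len(self.quarter_labels) != len(self.n):
            raise ValueError("quarter_labels length must match the series")
        if (self.stream_events is None) != (self.stream_periods is None):
            raise ValueError("stream_events and stream_periods go together")
        if self.stream_events is not None:
            self.stream_events = np.asarray(self.stream_events, dtype=np.int64)
            self.stream_periods = np.asarray(self.stream_periods, dtype=np.int64)
            if self.stream_events.shape != self.stream_periods.shape:
                raise ValueError("patient stream arrays must share a shape")
            if not np.isin(self.stream_events, (0, 1)).all():
                raise ValueError("patient stream outcomes must be 0/1")
            if np.any(np.diff(self.stream_periods) < 0):
                raise ValueError("patient stream must be ordered by period")
            for t in range(1, len(self.n) + 1):
                mask = self.stream_periods == t
                if mask.sum() != self.n[t - 1] or self.stream_events[mask].sum() != self.x[t - 1]:
                    raise ValueError(f"patient stream inconsistent with counts in period {t}")

    def __len__(self) -> int:
        return int(self.n.shape[0])

    @property
    def rates(self) -> np.ndarray:
        """Per-period sample proportions; NaN where ``n_t = 0``."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n > 0, self.x / np.maximum(self.n, 1), np.nan)

    def as_stream(self, order: str = "interleaved", seed: Optional[int] = None):
        """Return (events, periods) arrays, expanding counts if no stream is stored.

        ``order`` controls within-period placement of events when expanding:
        ``"events_first"`` is deterministic; ``"interleaved"`` shuffles each
        period with ``seed``.  Within-period order only affects the patient
        index at which a Bernoulli CUSUM alarm fires, never the alarm quarter
        of an end-of-period crossing.
        """
        if self.stream_events is not None:
            return self.stream_events.copy(), self.stream_periods.copy()
        rng = np.random.default_rng(seed)
        events, periods = [], []
        for t, (nt, xt) in enumerate(zip(self.n, self.x), start=1):
            block = np.zeros(int(nt), dtype=np.int64)
            block[: int(xt)] = 1
            if order == "interleaved":
                rng.shuffle(block)
            events.append(block)
            periods.append(np.full(int(nt), t, dtype=np.int64))
        return (
            np.concatenate(events) if events else np.empty(0, np.int64),
            np.concatenate(periods) if periods else np.empty(0, np.int64),
        )

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        labels = (
            list(self.quarter_labels)
            if self.quarter_labels is not None
            else ["" for _ in range(len(self))]
        )
        return pd.DataFrame(
            {
                "practice_id": self.practice_id or "",
                "quarter_index": np.arange(1, len(self) + 1),
                "quarter_label": labels,
                "n_eligible": self.n,
                "n_events": self.x,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "QuarterlySeries":
        frame = frame.sort_values("quarter_index")
        practice = frame["practice_id"].iloc[0] if len(frame) else None
        labels = frame["quarter_label"].astype(str).tolist() if len(frame) else None
        return cls(
            n=frame["n_eligible"].to_numpy(),
            x=frame["n_events"].to_numpy(),
            practice_id=None if practice in ("", None) else str(practice),
            quarter_labels=labels,
        )

    @classmethod
    def from_csv(cls, path) -> "QuarterlySeries":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False, na_values=[]))


# ---------------------------------------------------------------------------
# Chart specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChartSpec:
    """Chart family plus every tuning parameter needed to evaluate it.

    ``limit`` is the sigma-multiplier ``L`` for the p-chart and EWMA and the
    CUSUM decision interval ``h`` for the two CUSUM families.  ``p1`` (the
    design out-of-control rate) is required by the CUSUMs only; ``lam`` is
    the EWMA smoothing weight.
    """

    family: ChartFamily
    p0: float
    limit: float
    p1: Optional[float] = None
    lam: Optional[float] = None
    sidedness: str = "upper"

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ChartFamily.coerce(self.family))
        _check_probability("p0", self.p0, open_interval=True)
        if self.limit <= 0:
            raise ValueError(f"limit must be positive; got {self.limit}")
        if self.sidedness not in ("upper", "two_sided"):
            raise ValueError("sidedness must be 'upper' or 'two_sided'")
        if self.family in (ChartFamily.WB_CUSUM, ChartFamily.BERNOULLI_CUSUM):
            if self.p1 is None:
                raise ValueError("CUSUM charts require a design rate p1")
            _check_probability("p1", self.p1, open_interval=True)
            if self.p1 == self.p0:
                raise ValueError("degenerate CUSUM design: p1 must differ from p0")
        if self.family is ChartFamily.EWMA:
            if self.lam is None:
                raise ValueError("EWMA requires a smoothing weight lam")
            if not 0.0 < self.lam <= 1.0:
                raise ValueError(f"lam must lie in (0, 1]; got {self.lam}")

    def with_limit(self, limit: float) -> "ChartSpec":
        return replace(self, limit=limit)


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------


@dataclass
class ChartResult:
    """Per-period statistics, limits and signal flags for one evaluation.

    ``display_statistic`` carries the cumulative observed-minus-expected
    count ``Σ_{i≤t}(x_i − n_i p0)`` for the CUSUM families — the "golf score
    relative to par" that is plotted — while signalling always uses the
    floored likelihood-ratio statistic.  For the Bernoulli CUSUM the
    per-patient trajectory is kept in the ``stream_*`` fields.
    """

    family: ChartFamily
    statistic: np.ndarray
    center: np.ndarray
    lcl: np.ndarray
    ucl: np.ndarray
    signal: np.ndarray
    skipped: np.ndarray
    first_signal_period: Optional[int] = None
    display_statistic: Optional[np.ndarray] = None
    stream_statistic: Optional[np.ndarray] = None
    stream_periods: Optional[np.ndarray] = None
    stream_signal: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "period": np.arange(1, len(self.statistic) + 1),
                "statistic": self.statistic,
                "center": self.center,
                "lcl": self.lcl,
                "ucl": self.ucl,
                "signal": self.signal.astype(bool),
                "skipped": self.skipped.astype(bool),
            }
        )
        if self.display_statistic is not None:
            frame["display_statistic"] = self.display_statistic
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "family": self.family.value,
            "first_signal_period": self.first_signal_period,
            "periods": json.loads(self.to_frame().to_json(orient="records")),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text


def _first_signal(signal: np.ndarray) -> Optional[int]:
    hits = np.flatnonzero(signal)
    return int(hits[0]) + 1 if hits.size else None


# ---------------------------------------------------------------------------
# p-chart
# ---------------------------------------------------------------------------


def pchart_evaluate(
    series: QuarterlySeries,
    p0: float,
    L: float,
    sidedness: str = "upper",
) -> ChartResult:
    """Evaluate a p-chart: proportions against ``p0 ± L·sqrt(p0(1−p0)/n_t)``.

    Signals use strict inequality (``p̂_t > UCL_t``; two-sided adds
    ``p̂_t < LCL_t``).  Zero-volume periods carry no limits and are flagged
    as skipped.
    """
    _check_probability("p0", p0, open_interval=True)
    if L <= 0:
        raise ValueError("L must be positive")
    T = len(series)
    phat = series.rates
    skipped = series.n == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        half = L * np.sqrt(p0 * (1 - p0) / np.where(skipped, np.nan, series.n))
    ucl = p0 + half
    lcl = np.maximum(0.0, p0 - half)
    signal = np.zeros(T, dtype=bool)
    ok = ~skipped
    signal[ok] = phat[ok] > ucl[ok]
    if sidedness == "two_sided":
        signal[ok] |= phat[ok] < lcl[ok]
    elif sidedness != "upper":
        raise ValueError("sidedness must be 'upper' or 'two_sided'")
    return ChartResult(
        family=ChartFamily.P_CHART,
        statistic=phat,
        center=np.full(T, p0),
        lcl=lcl,
        ucl=ucl,
        signal=signal,
        skipped=skipped,
        first_signal_period=_first_signal(signal),
    )


# ---------------------------------------------------------------------------
# CUSUM charts
# ---------------------------------------------------------------------------


def cusum_weights(p0: float, p1: float) -> tuple[float, float]:
    """Bernoulli log-likelihood-ratio increments for a designed shift p0 → p1.

    Returns ``(w_event, w_nonevent)`` = ``(ln(p1/p0), ln((1−p1)/(1−p0)))``.
    For an upward design (``p1 > p0``) the event weight is positive and the
    non-event weight negative, so the floored cumulative sum drifts down
    in control and climbs under the shift.
    """
    _check_probability("p0", p0, open_interval=True)
    _check_probability("p1", p1, open_interval=True)
    if p1 == p0:
        raise ValueError("degenerate CUSUM design: p1 must differ from p0")
    return math.log(p1 / p0), math.log((1 - p1) / (1 - p0))


def wb_cusum_evaluate(
    series: QuarterlySeries,
    p0: float,
    p1: float,
    h: float,
    reset_on_signal: bool = False,
) -> ChartResult:
    """Weighted binomial CUSUM on per-period counts.

    Decision statistic ``S_t = max(0, S_{t−1} + x_t w_e + (n_t − x_t) w_n)``
    with a signal when ``S_t ≥ h``.  The plotted display statistic is the
    unreset observed-minus-expected sum ``Σ(x_i − n_i p0)``.
    """
    if h <= 0:
        raise ValueError("decision interval h must be positive")
    w_event, w_nonevent = cusum_weights(p0, p1)
    T = len(series)
    stat = np.zeros(T)
    signal = np.zeros(T, dtype=bool)
    s = 0.0
    for t in range(T):
        s = max(0.0, s + series.x[t] * w_event + (series.n[t] - series.x[t]) * w_nonevent)
        stat[t] = s
        if s >= h:
            signal[t] = True
            if reset_on_signal:
                s = 0.0
    display = np.cumsum(series.x - series.n * p0)
    return ChartResult(
        family=ChartFamily.WB_CUSUM,
        statistic=stat,
        center=np.zeros(T),
        lcl=np.zeros(T),
        ucl=np.full(T, h),
        signal=signal,
        skipped=series.n == 0,
        first_signal_period=_first_signal(signal),
        display_statistic=display,
    )


def bernoulli_cusum_evaluate(
    stream: Union[QuarterlySeries, np.ndarray, Sequence[int]],
    p0: float,
    p1: float,
    h: float,
    periods: Optional[Sequence[int]] = None,
    reset_on_signal: bool = False,
) -> ChartResult:
    """Bernoulli CUSUM updated patient-by-patient.

    ``stream`` is either a :class:`QuarterlySeries` carrying a patient
    stream or an array of binary outcomes with a parallel ``periods`` array
    of 1-based period labels.  ``S_i = max(0, S_{i−1} + w)`` with the event
    or non-event weight, signalling at the first ``S_i ≥ h``; the alarm is
    mapped to the period containing the alarming patient.
    """
    if h <= 0:
        raise ValueError("decision interval h must be positive")
    if isinstance(stream, QuarterlySeries):
        events, labels = stream.as_stream(order="events_first")
        if stream.stream_events is None and np.any(stream.x * (stream.n - stream.x) > 0):
            # counts alone do not pin down within-period ordering
            events, labels = stream.as_stream()
    else:
        events = np.asarray(stream, dtype=np.int64)
        if periods is None:
            raise ValueError("a raw outcome stream needs period labels")
        labels = np.asarray(periods, dtype=np.int64)
        if labels.shape != events.shape:
            raise ValueError("periods must parallel the outcome stream")
    if events.size == 0:
        raise ValueError("patient stream is empty")
    w_event, w_nonevent = cusum_weights(p0, p1)
    s = 0.0
    stat = np.zeros(events.size)
    sig = np.zeros(events.size, dtype=bool)
    for i, y in enumerate(events):
        s = max(0.0, s + (w_event if y else w_nonevent))
        stat[i] = s
        if s >= h:
            sig[i] = True
            if reset_on_signal:
                s = 0.0
    T = int(labels.max())
    per_signal = np.zeros(T, dtype=bool)
    per_stat = np.zeros(T)
    counts = np.zeros(T, dtype=np.int64)
    events_per = np.zeros(T, dtype=np.int64)
    for t in range(1, T + 1):
        mask = labels == t
        counts[t - 1] = mask.sum()
        events_per[t - 1] = events[mask].sum()
        if mask.any():
            per_stat[t - 1] = stat[mask][-1]
            per_signal[t - 1] = sig[mask].any()
    display = np.cumsum(events_per - counts * p0)
    return ChartResult(
        family=ChartFamily.BERNOULLI_CUSUM,
        statistic=per_stat,
        center=np.zeros(T),
        lcl=np.zeros(T),
        ucl=np.full(T, h),
        signal=per_signal,
        skipped=counts == 0,
        first_signal_period=_first_signal(per_signal),
        display_statistic=display,
        stream_statistic=stat,
        stream_periods=labels,
        stream_signal=sig,
    )


# ---------------------------------------------------------------------------
# EWMA
# ---------------------------------------------------------------------------


def ewma_evaluate(
    series: QuarterlySeries,
    p0: float,
    lam: float,
    L: float,
    sidedness: str = "upper",
) -> ChartResult:
    """EWMA chart for proportions with exact time-varying variance limits.

    ``Z_0 = p0``; ``Z_t = λ p̂_t + (1−λ) Z_{t−1}``;
    ``Var_t = p0(1−p0) λ² Σ_{i≤t} (1−λ)^{2(t−i)} / n_i`` so early periods get
    tighter limits than the asymptotic band.  With ``λ = 1`` the chart
    reduces exactly to the p-chart.  Zero-volume periods carry ``Z`` forward
    unchanged and are flagged as skipped.
    """
    _check_probability("p0", p0, open_interval=True)
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"lam must lie in (0, 1]; got {lam}")
    if L <= 0:
        raise ValueError("L must be positive")
    if sidedness not in ("upper", "two_sided"):
        raise ValueError("sidedness must be 'upper' or 'two_sided'")
    T = len(series)
    phat = series.rates
    z = p0
    var_factor = 0.0  # Σ λ²(1−λ)^{2(t−i)} / n_i, updated recursively
    stat = np.full(T, np.nan)
    ucl = np.full(T, np.nan)
    lcl = np.full(T, np.nan)
    signal = np.zeros(T, dtype=bool)
    skipped = series.n == 0
    for t in range(T):
        if skipped[t]:
            stat[t] = z
            continue
        z = lam * phat[t] + (1 - lam) * z
        var_factor = lam * lam / series.n[t] + (1 - lam) ** 2 * var_factor
        half = L * math.sqrt(p0 * (1 - p0) * var_factor)
        stat[t] = z
        ucl[t] = p0 + half
        lcl[t] = max(0.0, p0 - half)
        signal[t] = z > ucl[t] or (sidedness == "two_sided" and z < lcl[t])
    return ChartResult(
        family=ChartFamily.EWMA,
        statistic=stat,
        center=np.full(T, p0),
        lcl=lcl,
        ucl=ucl,
        signal=signal,
        skipped=skipped,
        first_signal_period=_first_signal(signal),
    )


# ---------------------------------------------------------------------------
# Dispatch and run length
# ---------------------------------------------------------------------------


def evaluate(series: QuarterlySeries, spec: ChartSpec, **kwargs) -> ChartResult:
    """Evaluate ``series`` under ``spec``, dispatching on the chart family."""
    fam = spec.family
    if fam is ChartFamily.P_CHART:
        return pchart_evaluate(series, spec.p0, spec.limit, spec.sidedness)
    if fam is ChartFamily.WB_CUSUM:
        return wb_cusum_evaluate(series, spec.p0, spec.p1, spec.limit, **kwargs)
    if fam is ChartFamily.BERNOULLI_CUSUM:
        return bernoulli_cusum_evaluate(series, spec.p0, spec.p1, spec.limit, **kwargs)
    if fam is ChartFamily.EWMA:
        return ewma_evaluate(series, spec.p0, spec.lam, spec.limit, spec.sidedness)
    raise ValueError(f"unknown chart family {fam!r}")


def run_length(result: ChartResult) -> Optional[int]:
    """First signalling period of a chart evaluation, or None if silent."""
    return result.first_signal_period
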