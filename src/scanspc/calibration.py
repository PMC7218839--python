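"""Limit calibration: standardize charts to a common false-signal budget.

Charts are only comparable once they share the same in-control operating
characteristic.  Following the study design, every chart's limit parameter
(sigma-multiplier ``L`` or decision interval ``h``) is tuned by Monte Carlo
bisection so the probability of at least one alarm within a fixed horizon
(default 20 in-control quarters, i.e. 5 years) equals a common target
(default 10 %).

Common random numbers make the empirical operating characteristic exactly
non-increasing in the limit, so bisection is valid; since no chart's
trajectory depends on its limit, each evaluation reuses one cached set of
per-run maxima.  For charts whose achievable probabilities are discrete at
the given sample size — notably the p-chart at n = 26, where the
20-quarter false-signal probability jumps 28.4 % → 6.7 % → 1.2 % as the
limit crosses successive count thresholds — the calibrated limit is the
nearest achievable one, and the result discloses the gap and both flanking
achievable values.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

import numpy as np

from ._sim import max_statistics
from .charts import ChartFamily, ChartSpec

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "FalseSignalEstimate",
    "CalibrationError",
    "per_period_alpha",
    "false_signal_probability",
    "calibrate_limit",
]


class CalibrationError(RuntimeError):
    """Raised when the bracket does not straddle the target probability."""


def per_period_alpha(target: float, horizon_T: int) -> float:
    """Constant per-period signal probability yielding ``target`` over the horizon.

    ``α* = 1 − (1 − target)^(1/T)``: a memoryless chart signalling each
    period with probability ``α*`` has exactly probability ``target`` of at
    least one alarm in ``T`` periods.  Closed-form reference point for the
    p-chart; the charts with memory are calibrated by simulation.
    """
    if not 0.0 <= target < 1.0:
        raise ValueError(f"target must lie in [0, 1); got {target}")
    if horizon_T < 1:
        raise ValueError("horizon_T must be positive")
    return 1.0 - (1.0 - target) ** (1.0 / horizon_T)


@dataclass(frozen=True)
class CalibrationSpec:
    """Everything needed to calibrate one chart family.

    ``bracket`` must straddle the target: the false-signal probability at
    the lower limit must be ≥ target and at the upper limit ≤ target.
    ``tolerance`` is on the achieved probability.
    """

    family: ChartFamily
    p0: float = 0.059
    p1: Optional[float] = None
    lam: Optional[float] = None
    n_per_period: int = 26
    horizon_T: int = 20
    target_false_signal: float = 0.10
    reps: int = 100_000
    seed: int = 0
    bracket: Optional[Tuple[float, float]] = None
    tolerance: float = 0.002
    sidedness: str = "upper"

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ChartFamily.coerce(self.family))
        if not 0.0 < self.target_false_signal < 1.0:
            raise ValueError("target_false_signal must lie in (0, 1)")
        if self.horizon_T < 1 or self.n_per_period < 1 or self.reps < 1:
            raise ValueError("horizon_T, n_per_period and reps must be positive")
        if self.bracket is not None and not self.bracket[0] < self.bracket[1]:
            raise ValueError("bracket must satisfy lo < hi")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def default_bracket(self) -> Tuple[float, float]:
        if self.family in (ChartFamily.P_CHART, ChartFamily.EWMA):
            return (0.25, 8.0)
        return (0.05, 40.0)


@dataclass
class FalseSignalEstimate:
    """Monte Carlo estimate of the horizon false-signal probability."""

    probability: float
    se: float
    reps: int
    seed: int


@dataclass
class CalibrationResult:
    """Calibrated limit with its achieved operating characteristic.

    ``achieved`` is the common-random-number estimate at ``limit``; the gap
    to the target is never hidden.  ``neighbor_below``/``neighbor_above``
    are the flanking achievable (limit, probability) pairs one lattice step
    away — informative for effectively-discrete charts such as the p-chart.
    """

    family: ChartFamily
    limit: float
    achieved: float
    achieved_se: float
    target: float
    neighbor_below: Tuple[float, float]
    neighbor_above: Tuple[float, float]
    reps: int
    seed: int
    under_resolved: bool = False

    @property
    def gap(self) -> float:
        return self.achieved - self.target

    def spec(self, cal: "CalibrationSpec") -> ChartSpec:
        """The calibrated :class:`ChartSpec` for downstream evaluation."""
        return ChartSpec(
            family=self.family,
            p0=cal.p0,
            p1=cal.p1,
            lam=cal.lam,
            limit=self.limit,
            sidedness=cal.sidedness,
        )

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["family"] = self.family.value
        payload["gap"] = self.gap
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text


def _maxima(cal: CalibrationSpec) -> np.ndarray:
    return max_statistics(
        family=cal.family,
        p0=cal.p0,
        n_per_period=cal.n_per_period,
        horizon_T=cal.horizon_T,
        reps=cal.reps,
        seed=cal.seed,
        p1=cal.p1,
        lam=cal.lam,
        sidedness=cal.sidedness,
    )


def _crossing_fraction(maxima: np.ndarray, family: ChartFamily, limit: float) -> float:
    if family in (ChartFamily.WB_CUSUM, ChartFamily.BERNOULLI_CUSUM):
        return float(np.count_nonzero(maxima >= limit)) / maxima.size
    return float(np.count_nonzero(maxima > limit)) / maxima.size


def false_signal_probability(
    spec: ChartSpec,
    n_per_period: int = 26,
    horizon_T: int = 20,
    reps: int = 100_000,
    seed: int = 0,
) -> FalseSignalEstimate:
    """Probability of any alarm within ``horizon_T`` in-control periods.

    Simulated at ``spec.p0`` with a common-random-number stream keyed by
    ``seed``: repeated calls with the same seed evaluate different limits
    on identical trajectories.
    """
    maxima = max_statistics(
        family=spec.family,
        p0=spec.p0,
        n_per_period=n_per_period,
        horizon_T=horizon_T,
        reps=reps,
        seed=seed,
        p1=spec.p1,
        lam=spec.lam,
        sidedness=spec.sidedness,
    )
    p = _crossing_fraction(maxima, spec.family, spec.limit)
    return FalseSignalEstimate(
        probability=p,
        se=math.sqrt(p * (1.0 - p) / reps),
        reps=reps,
        seed=seed,
    )


def calibrate_limit(cal: CalibrationSpec) -> CalibrationResult:
    """Calibrate the limit parameter to the target false-signal probability.

    Bisection on the limit over ``cal.bracket`` using common random
    numbers; the final limit is snapped into the middle of the empirical
    lattice gap whose achieved probability is nearest the target, making
    the strict-``>`` and ``≥`` crossing conventions coincide and the
    result robust to floating-point ties.  A ``tolerance ≥ 1`` returns the
    bracket midpoint flagged as under-resolved.
    """
    lo, hi = cal.bracket if cal.bracket is not None else cal.default_bracket()
    target = cal.target_false_signal
    if cal.tolerance >= 1.0:
        mid = 0.5 * (lo + hi)
        maxima = _maxima(cal)
        a = _crossing_fraction(maxima, cal.family, mid)
        se = math.sqrt(a * (1 - a) / cal.reps)
        return CalibrationResult(
            family=cal.family,
            limit=mid,
            achieved=a,
            achieved_se=se,
            target=target,
            neighbor_below=(lo, _crossing_fraction(maxima, cal.family, lo)),
            neighbor_above=(hi, _crossing_fraction(maxima, cal.family, hi)),
            reps=cal.reps,
            seed=cal.seed,
            under_resolved=True,
        )

    maxima = _maxima(cal)
    f_lo = _crossing_fraction(maxima, cal.family, lo)
    f_hi = _crossing_fraction(maxima, cal.family, hi)
    if f_hi > target:
        raise CalibrationError(
            f"bracket ({lo}, {hi}) does not straddle target {target}: "
            f"achieved {f_lo:.4f} at lo, {f_hi:.4f} at hi"
        )
    if f_lo < target:
        # Distinguish a mis-placed bracket from a target no positive limit
        # can reach (e.g. a high target for a discrete upper-sided chart).
        f_floor = _crossing_fraction(maxima, cal.family, 1e-9)
        if f_floor >= target:
            raise CalibrationError(
                f"bracket ({lo}, {hi}) does not straddle target {target}: "
                f"achieved {f_lo:.4f} at lo, {f_hi:.4f} at hi"
            )
    # Bisection under common random numbers (f is exactly non-increasing).
    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        f_mid = _crossing_fraction(maxima, cal.family, mid)
        if abs(f_mid - target) <= cal.tolerance and b - a <= 1e-6 * (hi - lo):
            break
        if f_mid >= target:
            a = mid
        else:
            b = mid
        if b - a <= 1e-12 * (hi - lo):
            break

    # Snap to the nearest achievable step: candidate limits sit in the open
    # gaps between adjacent distinct simulated maxima, where > and >= agree.
    values = np.unique(maxima)
    values = values[(values > lo) & (values < hi)]
    sorted_max = np.sort(maxima)
    # tail_ge[i] = P(max >= values[i])
    tail_ge = 1.0 - np.searchsorted(sorted_max, values, side="left") / maxima.size
    candidates = np.concatenate([tail_ge, [_crossing_fraction(maxima, cal.family, hi)]])
    best = int(np.argmin(np.abs(candidates - target)))

    def gap_limit(idx: int) -> float:
        if idx >= len(values):
            return 0.5 * (values[-1] + hi) if len(values) else hi
        upper = values[idx]
        lower = values[idx - 1] if idx > 0 else lo
        return 0.5 * (lower + upper)

    limit = gap_limit(best)
    achieved = float(candidates[best])
    se = math.sqrt(achieved * (1 - achieved) / cal.reps)
    below = max(best - 1, 0)
    above = min(best + 1, len(candidates) - 1)
    return CalibrationResult(
        family=cal.family,
        limit=float(limit),
        achieved=achieved,
        achieved_se=se,
        target=target,
        neighbor_below=(float(gap_limit(below)), float(candidates[below])),
        neighbor_above=(float(gap_limit(above)), float(candidates[above])),
        reps=cal.reps,
        seed=cal.seed,
    )
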