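"""Vectorized Monte Carlo kernels shared by calibration and ARL estimation.

Two primitives cover everything the package simulates:

* :func:`max_statistics` — per-replication supremum of the chart's
  limit-comparable statistic over a fixed in-control horizon.  Because no
  chart's trajectory depends on its limit parameter, the false-signal
  probability at limit ``l`` is just the tail frequency of these maxima,
  which makes the empirical operating characteristic exactly monotone in
  ``l`` under common random numbers.
* :func:`run_lengths` — first-signal periods under a constant true rate,
  with censoring at ``max_periods``.

Both draw from ``numpy.random.default_rng(seed)`` and are deterministic
given (arguments, seed).
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .charts import ChartFamily, ChartSpec


def _weights(p0: float, p1: float) -> Tuple[float, float]:
    return math.log(p1 / p0), math.log((1 - p1) / (1 - p0))


def max_statistics(
    family: ChartFamily,
    p0: float,
    n_per_period: int,
    horizon_T: int,
    reps: int,
    seed: int,
    p1: Optional[float] = None,
    lam: Optional[float] = None,
    sidedness: str = "upper",
) -> np.ndarray:
    """Per-replication supremum of the standardized chart statistic.

    p-chart: ``max_t (p̂_t − p0)/sqrt(p0(1−p0)/n)`` (absolute value when
    two-sided) — compared to ``L`` with strict inequality.  EWMA: the same
    on the standardized EWMA statistic.  CUSUMs: ``max S`` over the horizon
    (per patient for the Bernoulli chart) — compared to ``h`` with ``≥``.
    """
    family = ChartFamily.coerce(family)
    rng = np.random.default_rng(seed)
    q0 = p0 * (1.0 - p0)
    if family is ChartFamily.P_CHART:
        x = rng.binomial(n_per_period, p0, size=(reps, horizon_T))
        z = (x / n_per_period - p0) / math.sqrt(q0 / n_per_period)
        if sidedness == "two_sided":
            z = np.abs(z)
        return z.max(axis=1)
    if family is ChartFamily.EWMA:
        if lam is None:
            raise ValueError("EWMA needs a smoothing weight lam")
        x = rng.binomial(n_per_period, p0, size=(reps, horizon_T))
        z = np.full(reps, p0)
        var_factor = 0.0
        best = np.full(reps, -np.inf)
        for t in range(horizon_T):
            z = lam * (x[:, t] / n_per_period) + (1 - lam) * z
            var_factor = lam * lam / n_per_period + (1 - lam) ** 2 * var_factor
            std = (z - p0) / math.sqrt(q0 * var_factor)
            if sidedness == "two_sided":
                std = np.abs(std)
            np.maximum(best, std, out=best)
        return best
    if family in (ChartFamily.WB_CUSUM, ChartFamily.BERNOULLI_CUSUM):
        if p1 is None:
            raise ValueError("CUSUM charts need a design rate p1")
        if sidedness != "upper":
            raise ValueError("the floored CUSUM form is one-sided (upper)")
        w_event, w_nonevent = _weights(p0, p1)
        s = np.zeros(reps)
        best = np.zeros(reps)
        if family is ChartFamily.WB_CUSUM:
            x = rng.binomial(n_per_period, p0, size=(reps, horizon_T))
            for t in range(horizon_T):
                s = np.maximum(
                    0.0, s + x[:, t] * w_event + (n_per_period - x[:, t]) * w_nonevent
                )
                np.maximum(best, s, out=best)
        else:
            for _ in range(horizon_T):
                u = rng.random(size=(reps, n_per_period))
                for i in range(n_per_period):
                    s = np.maximum(0.0, s + np.where(u[:, i] < p0, w_event, w_nonevent))
                    np.maximum(best, s, out=best)
        return best
    raise ValueError(f"unknown chart family {family!r}")


def run_lengths(
    spec: ChartSpec,
    true_rate: float,
    n_per_period: int,
    reps: int,
    max_periods: int,
    seed: int,
    burn_in_periods: int = 0,
    burn_in_rate: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """First-signal periods for ``reps`` independent runs at ``true_rate``.

    Runs start at period 1 with the chart in its initial state (``S = 0``,
    ``Z = p0``).  With ``burn_in_periods > 0`` the chart first digests that
    many periods at ``burn_in_rate`` (default ``p0``) with signals ignored,
    and the run length counts periods after the burn-in.  Returns
    ``(run_length, censored)``; censored runs are recorded at
    ``max_periods``.
    """
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError(f"true_rate must lie in [0, 1]; got {true_rate}")
    if max_periods < 1:
        raise ValueError("max_periods must be positive")
    family = spec.family
    rng = np.random.default_rng(seed)
    p0, limit = spec.p0, spec.limit
    q0 = p0 * (1.0 - p0)
    rl = np.full(reps, max_periods, dtype=np.int64)
    alive = np.ones(reps, dtype=bool)
    if burn_in_rate is None:
        burn_in_rate = p0

    if family is ChartFamily.P_CHART:
        se = math.sqrt(q0 / n_per_period)
        ucl = p0 + limit * se
        lcl = max(0.0, p0 - limit * se)
        # memoryless: burn-in has no effect beyond consuming draws
        if burn_in_periods:
            rng.binomial(n_per_period, burn_in_rate, size=(reps, burn_in_periods))
        t = 0
        while alive.any() and t < max_periods:
            t += 1
            phat = rng.binomial(n_per_period, true_rate, size=reps) / n_per_period
            sig = phat > ucl
            if spec.sidedness == "two_sided":
                sig |= phat < lcl
            hit = alive & sig
            rl[hit] = t
            alive &= ~sig
        return rl, alive

    if family is ChartFamily.EWMA:
        lam = spec.lam
        z = np.full(reps, p0)
        var_factor = 0.0
        for _ in range(burn_in_periods):
            phat = rng.binomial(n_per_period, burn_in_rate, size=reps) / n_per_period
            z = lam * phat + (1 - lam) * z
            var_factor = lam * lam / n_per_period + (1 - lam) ** 2 * var_factor
        t = 0
        while alive.any() and t < max_periods:
            t += 1
            phat = rng.binomial(n_per_period, true_rate, size=reps) / n_per_period
            z = lam * phat + (1 - lam) * z
            var_factor = lam * lam / n_per_period + (1 - lam) ** 2 * var_factor
            half = limit * math.sqrt(q0 * var_factor)
            sig = z > p0 + half
            if spec.sidedness == "two_sided":
                sig |= z < max(0.0, p0 - half)
            hit = alive & sig
            rl[hit] = t
            alive &= ~sig
        return rl, alive

    w_event, w_nonevent = _weights(p0, spec.p1)
    s = np.zeros(reps)
    if family is ChartFamily.WB_CUSUM:
        for _ in range(burn_in_periods):
            x = rng.binomial(n_per_period, burn_in_rate, size=reps)
            s = np.maximum(0.0, s + x * w_event + (n_per_period - x) * w_nonevent)
        t = 0
        while alive.any() and t < max_periods:
            t += 1
            x = rng.binomial(n_per_period, true_rate, size=reps)
            s = np.maximum(0.0, s + x * w_event + (n_per_period - x) * w_nonevent)
            hit = alive & (s >= spec.limit)
            rl[hit] = t
            alive &= ~hit
        return rl, alive

    if family is ChartFamily.BERNOULLI_CUSUM:
        for _ in range(burn_in_periods):
            u = rng.random(size=(reps, n_per_period))
            for i in range(n_per_period):
                s = np.maximum(0.0, s + np.where(u[:, i] < burn_in_rate, w_event, w_nonevent))
        t = 0
        crossed = np.zeros(reps, dtype=bool)
        while alive.any() and t < max_periods:
            t += 1
            u = rng.random(size=(reps, n_per_period))
            crossed[:] = False
            for i in range(n_per_period):
                s = np.maximum(0.0, s + np.where(u[:, i] < true_rate, w_event, w_nonevent))
                crossed |= s >= spec.limit
            hit = alive & crossed
            rl[hit] = t
            alive &= ~hit
        return rl, alive

    raise ValueError(f"unknown chart family {family!r}")
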