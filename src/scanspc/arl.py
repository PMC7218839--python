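"""Out-of-control run-length estimation, chart comparison, and rate sweeps.

A run starts at period 1 with the chart in its initial state (``S = 0``,
``Z = p0``) and the process already at the true rate; the run length is the
first signalling quarter (for the Bernoulli CUSUM, the quarter containing
the alarming patient).  The ARL — the mean run length over many
independent replications — is the sensitivity currency in which the four
charts are compared: after identical in-control calibration, a lower
out-of-control ARL means faster detection.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._sim import run_lengths as _run_lengths
from .charts import ChartFamily, ChartSpec

__all__ = [
    "ARLEstimate",
    "RunLengthComparison",
    "SweepTable",
    "simulate_run_length",
    "run_length_sample",
    "estimate_arl",
    "compare_run_lengths",
    "arl_sweep",
]

DEFAULT_CENSOR_CEILING = 0.001  # flag estimates with > 0.1 % censored runs


@dataclass
class ARLEstimate:
    """Summary of a run-length sample for one chart × rate scenario.

    ``arl`` is the mean first-signal period in quarters (censored runs
    counted at ``max_periods``, biasing the mean low — hence the flag when
    censoring exceeds the ceiling); ``se`` the Monte Carlo standard error.
    """

    family: ChartFamily
    true_rate: float
    reps: int
    arl: float
    se: float
    median: float
    quantiles: Dict[str, float]
    censored: int
    max_periods: int
    n_per_period: int
    seed: int
    flagged: bool = False

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["family"] = self.family.value
        return payload


def run_length_sample(
    spec: ChartSpec,
    true_rate: float,
    n_per_period: int = 26,
    reps: int = 10_000,
    max_periods: int = 400,
    seed: int = 0,
    burn_in_periods: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Raw run-length sample: ``(run_lengths, censored)`` arrays."""
    if reps < 1:
        raise ValueError("reps must be positive")
    return _run_lengths(
        spec,
        true_rate,
        n_per_period=n_per_period,
        reps=reps,
        max_periods=max_periods,
        seed=seed,
        burn_in_periods=burn_in_periods,
    )


def simulate_run_length(
    spec: ChartSpec,
    true_rate: float,
    n_per_period: int = 26,
    max_periods: int = 400,
    seed: int = 0,
    burn_in_periods: int = 0,
) -> Optional[int]:
    """Single simulated run length in periods; None if censored."""
    rl, censored = run_length_sample(
        spec,
        true_rate,
        n_per_period=n_per_period,
        reps=1,
        max_periods=max_periods,
        seed=seed,
        burn_in_periods=burn_in_periods,
    )
    return None if censored[0] else int(rl[0])


def estimate_arl(
    spec: ChartSpec,
    true_rate: float,
    n_per_period: int = 26,
    reps: int = 10_000,
    max_periods: int = 400,
    seed: int = 0,
    censor_ceiling: float = DEFAULT_CENSOR_CEILING,
    burn_in_periods: int = 0,
) -> ARLEstimate:
    """Monte Carlo ARL estimate with SE, quantiles and censoring disclosure."""
    if reps < 2:
        raise ValueError("reps must be at least 2 for an SE")
    rl, censored = run_length_sample(
        spec,
        true_rate,
        n_per_period=n_per_period,
        reps=reps,
        max_periods=max_periods,
        seed=seed,
        burn_in_periods=burn_in_periods,
    )
    qs = {f"q{int(100 * q)}": float(np.quantile(rl, q)) for q in (0.10, 0.25, 0.75, 0.90)}
    n_censored = int(censored.sum())
    return ARLEstimate(
        family=spec.family,
        true_rate=float(true_rate),
        reps=reps,
        arl=float(rl.mean()),
        se=float(rl.std(ddof=1) / math.sqrt(reps)),
        median=float(np.median(rl)),
        quantiles=qs,
        censored=n_censored,
        max_periods=max_periods,
        n_per_period=n_per_period,
        seed=seed,
        flagged=n_censored / reps > censor_ceiling,
    )


@dataclass
class RunLengthComparison:
    """Two-sample comparison of run-length distributions.

    Primary: two-sided Mann–Whitney U (run lengths are highly skewed, so a
    rank test is the honest default).  Secondary: Welch's t on log run
    lengths.  Identical constant samples get p = 1 by convention.
    """

    p_value: float
    u_statistic: float
    median_a: float
    median_b: float
    arl_a: float
    arl_b: float
    arl_difference: float
    p_value_welch_log: float


def compare_run_lengths(
    sample_a: Sequence[int],
    sample_b: Sequence[int],
) -> RunLengthComparison:
    """Rank-based comparison of two run-length samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each run-length sample needs at least 2 observations")
    if np.any(a < 1) or np.any(b < 1):
        raise ValueError("run lengths must be >= 1")
    constant = a.std() == 0 and b.std() == 0
    if constant and a[0] == b[0]:
        p_value, u_stat, p_welch = 1.0, a.size * b.size / 2.0, 1.0
    else:
        u_stat, p_value = stats.mannwhitneyu(a, b, alternative="two-sided")
        if constant:
            p_welch = 0.0
        else:
            _, p_welch = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
    return RunLengthComparison(
        p_value=float(p_value),
        u_statistic=float(u_stat),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        arl_a=float(a.mean()),
        arl_b=float(b.mean()),
        arl_difference=float(a.mean() - b.mean()),
        p_value_welch_log=float(p_welch),
    )


@dataclass
class SweepTable:
    """Chart × rate grid of ARL estimates."""

    estimates: List[ARLEstimate] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates:
            row = {
                "family": est.family.value,
                "rate": est.true_rate,
                "arl": est.arl,
                "se": est.se,
                "median": est.median,
                "censored": est.censored,
                "flagged": est.flagged,
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        text = json.dumps([e.to_dict() for e in self.estimates], indent=2)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text

    def for_family(self, family: ChartFamily) -> List[ARLEstimate]:
        family = ChartFamily.coerce(family)
        return sorted(
            (e for e in self.estimates if e.family is family),
            key=lambda e: e.true_rate,
        )


def arl_sweep(
    specs: Sequence[ChartSpec],
    rates: Sequence[float],
    n_per_period: int = 26,
    reps: int = 10_000,
    max_periods: int = 400,
    seed: int = 0,
) -> SweepTable:
    """ARL grid over calibrated specs × true rates.

    Each (chart, rate) cell draws from its own substream spawned from the
    base seed, so cells are independent and the whole table is reproducible
    from ``seed``.
    """
    cells = [(spec, rate) for spec in specs for rate in rates]
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(cells), 1)) % (2**31)
    table = SweepTable()
    for (spec, rate), cell_seed in zip(cells, child_seeds):
        table.estimates.append(
            estimate_arl(
                spec,
                rate,
                n_per_period=n_per_period,
                reps=reps,
                max_periods=max_periods,
                seed=int(cell_seed),
            )
        )
    return table
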