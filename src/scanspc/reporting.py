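"""Figures, end-to-end pipeline, configuration and logging.

The plotting layer never recomputes statistics: every marker comes straight
from a :class:`~scanspc.charts.ChartResult`, so figures and tables cannot
disagree.  ``run_pipeline`` chains synthetic registry → cohort →
calibration → charts/ARL → figures and tables, writing a manifest with
seeds and achieved-vs-target calibration probabilities — the reproducibility
record for every Monte Carlo claim the outputs make.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import __version__ as _version
from .arl import arl_sweep, compare_run_lengths, estimate_arl, run_length_sample
from .calibration import CalibrationResult, CalibrationSpec, calibrate_limit
from .charts import ChartFamily, ChartResult, ChartSpec, QuarterlySeries, evaluate
from .cohort import IndicationClass, aggregate_quarterly, apply_exclusions
from .synthetic import SyntheticConfig, generate_registry

__all__ = ["RunConfig", "PipelineError", "render_chart", "run_pipeline"]

logger = logging.getLogger("scanspc")

_FAMILY_TITLES = {
    ChartFamily.P_CHART: "p-chart",
    ChartFamily.WB_CUSUM: "Weighted binomial CUSUM",
    ChartFamily.BERNOULLI_CUSUM: "Bernoulli CUSUM",
    ChartFamily.EWMA: "EWMA",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; YAML round-trippable.

    Every random procedure receives a seed derived from ``seed`` via
    spawned substreams, so one integer reproduces the whole bundle.
    """

    seed: int = 0
    output_dir: str = "scanspc_output"
    # cohort options
    window_days: int = 30
    quarter_by: str = "entry"
    # chart / calibration design
    p0: float = 0.059
    p1: float = 0.114
    lam: float = 0.2
    n_per_period: int = 26
    horizon_T: int = 20
    target_false_signal: float = 0.10
    calibration_reps: int = 100_000
    sidedness: str = "upper"
    # ARL simulation
    arl_reps: int = 10_000
    max_periods: int = 400
    out_of_control_rate: float = 0.114
    sweep_rates: Tuple[float, ...] = ()
    sweep_reps: int = 10_000
    # synthetic registry
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    registry_csv: Optional[str] = None
    families: Tuple[str, ...] = tuple(f.value for f in ChartFamily)

    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["synthetic"] = dataclasses.asdict(self.synthetic)
        payload["synthetic"]["change_points"] = [
            list(cp) for cp in self.synthetic.change_points
        ]
        payload["sweep_rates"] = list(self.sweep_rates)
        payload["families"] = list(self.families)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            payload = yaml.safe_load(Path(source).read_text())
        else:
            payload = yaml.safe_load(str(source))
        synth = payload.pop("synthetic", {})
        synth["change_points"] = tuple(tuple(cp) for cp in synth.get("change_points", ()))
        payload["synthetic"] = SyntheticConfig(**synth)
        payload["sweep_rates"] = tuple(payload.get("sweep_rates", ()))
        payload["families"] = tuple(payload.get("families", ()))
        return cls(**payload)

    def chart_families(self) -> List[ChartFamily]:
        return [ChartFamily.coerce(f) for f in self.families]

    def calibration_spec(self, family: ChartFamily, seed: int) -> CalibrationSpec:
        family = ChartFamily.coerce(family)
        needs_p1 = family in (ChartFamily.WB_CUSUM, ChartFamily.BERNOULLI_CUSUM)
        return CalibrationSpec(
            family=family,
            p0=self.p0,
            p1=self.p1 if needs_p1 else None,
            lam=self.lam if family is ChartFamily.EWMA else None,
            n_per_period=self.n_per_period,
            horizon_T=self.horizon_T,
            target_false_signal=self.target_false_signal,
            reps=self.calibration_reps,
            seed=seed,
            sidedness=self.sidedness,
        )


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def render_chart(
    result: ChartResult,
    family: Optional[ChartFamily] = None,
    path=None,
    title: Optional[str] = None,
):
    """Render one chart evaluation as a publication-style figure.

    Plots the per-period statistic, center line and control limits, with
    signal markers at exactly the flagged periods of ``result``.  CUSUM
    figures show the observed-minus-expected display statistic with alarm
    arrows at the likelihood-ratio signal periods; the Bernoulli CUSUM is
    drawn per patient with quarter tick marks, so period spacing varies
    with volume.  Returns the matplotlib figure (saved to ``path`` if
    given).
    """
    family = ChartFamily.coerce(family) if family is not None else result.family
    if result.statistic.size == 0:
        raise ValueError("cannot render an empty chart result")
    periods = np.arange(1, result.statistic.size + 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    cusum = family in (ChartFamily.WB_CUSUM, ChartFamily.BERNOULLI_CUSUM)
    if family is ChartFamily.BERNOULLI_CUSUM and result.stream_statistic is not None:
        idx = np.arange(1, result.stream_statistic.size + 1)
        ax.step(idx, result.stream_statistic, where="post", lw=0.8, label="CUSUM statistic")
        ax.axhline(result.ucl[0], color="firebrick", ls="--", label="decision interval h")
        boundaries = np.flatnonzero(np.diff(result.stream_periods)) + 1
        for b in boundaries:
            ax.axvline(b + 0.5, color="0.85", lw=0.5, zorder=0)
        sig_idx = np.flatnonzero(result.stream_signal)
        if sig_idx.size:
            first = sig_idx[0]
            ax.annotate(
                "signal",
                xy=(first + 1, result.stream_statistic[first]),
                xytext=(first + 1, result.stream_statistic[first] * 1.15 + 0.3),
                arrowprops=dict(arrowstyle="->", color="firebrick"),
                color="firebrick",
            )
        ax.set_xlabel("patient index (quarter boundaries in grey)")
    elif cusum:
        ax.plot(periods, result.display_statistic, marker="o", ms=3, label="observed − expected")
        ax.axhline(0.0, color="0.4", lw=0.8)
        for t in np.flatnonzero(result.signal):
            ax.annotate(
                "signal",
                xy=(periods[t], result.display_statistic[t]),
                xytext=(periods[t], result.display_statistic[t] + 1.0),
                arrowprops=dict(arrowstyle="->", color="firebrick"),
                color="firebrick",
            )
        ax.set_xlabel("quarter")
    else:
        ax.plot(periods, result.statistic, marker="o", ms=3, label="statistic")
        ax.plot(periods, result.center, color="0.4", lw=0.8, label="center line")
        ax.plot(periods, result.ucl, color="firebrick", ls="--", lw=1.0, label="UCL")
        ax.plot(periods, result.lcl, color="firebrick", ls=":", lw=1.0, label="LCL")
        flagged = np.flatnonzero(result.signal)
        if flagged.size:
            ax.scatter(
                periods[flagged],
                result.statistic[flagged],
                marker="^",
                color="firebrick",
                zorder=5,
                label="signal",
            )
        ax.set_xlabel("quarter")
    ax.set_ylabel("proportion" if not cusum else "cumulative count")
    ax.set_title(title or _FAMILY_TITLES[family])
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # persist-partial-then-abort contract
                logger.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return decorator


def run_pipeline(config: RunConfig) -> dict:
    """Run synth/load → cohort → calibrate → charts + ARL → figures/tables.

    Returns the manifest (also written to ``manifest.json``): package
    version, seeds, cohort tally, calibrated limits with achieved
    false-signal probabilities, and the ARL table.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = np.random.SeedSequence(config.seed).generate_state(16) % (2**31)
    manifest: dict = {
        "package": "scanspc",
        "version": _version,
        "seed": int(config.seed),
        "config": yaml.safe_load(config.to_yaml()),
    }
    try:
        # --- registry -----------------------------------------------------
        @_stage("registry")
        def _registry():
            from .cohort import read_registry_csv, write_registry_csv

            if config.registry_csv is not None:
                return read_registry_csv(config.registry_csv)
            synth = dataclasses.replace(config.synthetic, seed=int(seeds[0]))
            records = generate_registry(synth)
            write_registry_csv(records, outdir / "registry.csv")
            return records

        records = _registry()

        @_stage("cohort")
        def _cohort():
            retained, tally = apply_exclusions(records, window_days=config.window_days)
            series = aggregate_quarterly(
                retained,
                class_filter=IndicationClass.NOT_INDICATED,
                quarter_by=config.quarter_by,
            )
            for practice, s in series.items():
                s.to_csv(outdir / f"series_{practice}.csv")
            return retained, tally, series

        _, tally, series_by_practice = _cohort()
        manifest["cohort"] = tally.as_dict()

        @_stage("calibrate")
        def _calibrate():
            results: Dict[str, CalibrationResult] = {}
            specs: Dict[str, ChartSpec] = {}
            for i, family in enumerate(config.chart_families()):
                cal = config.calibration_spec(family, seed=int(seeds[1 + i]))
                res = calibrate_limit(cal)
                results[family.value] = res
                specs[family.value] = res.spec(cal)
                logger.info(
                    "calibrated %s: limit=%.5f achieved=%.4f target=%.4f (gap %+.4f)",
                    family.value,
                    res.limit,
                    res.achieved,
                    res.target,
                    res.gap,
                )
            with open(outdir / "calibration.json", "w") as handle:
                json.dump(
                    {k: json.loads(v.to_json()) for k, v in results.items()},
                    handle,
                    indent=2,
                )
            return results, specs

        cal_results, specs = _calibrate()
        manifest["calibration"] = {
            k: {"limit": v.limit, "achieved": v.achieved, "target": v.target, "gap": v.gap}
            for k, v in cal_results.items()
        }

        @_stage("arl")
        def _arl():
            rows = []
            for i, (name, spec) in enumerate(specs.items()):
                est = estimate_arl(
                    spec,
                    config.out_of_control_rate,
                    n_per_period=config.n_per_period,
                    reps=config.arl_reps,
                    max_periods=config.max_periods,
                    seed=int(seeds[8 + i]),
                )
                rows.append(est.to_dict())
            import pandas as pd

            frame = pd.DataFrame(rows)
            frame.to_csv(outdir / "arl_table.csv", index=False)
            return rows

        manifest["arl_out_of_control"] = _arl()

        if config.sweep_rates:

            @_stage("sweep")
            def _sweep():
                table = arl_sweep(
                    list(specs.values()),
                    list(config.sweep_rates),
                    n_per_period=config.n_per_period,
                    reps=config.sweep_reps,
                    max_periods=config.max_periods,
                    seed=int(seeds[12]),
                )
                table.to_csv(outdir / "arl_sweep.csv")
                return table

            _sweep()

        @_stage("figures")
        def _figures():
            paths = []
            for practice, series in list(series_by_practice.items())[:1]:
                for name, spec in specs.items():
                    result = evaluate(series, spec)
                    path = outdir / f"chart_{name}_{practice}.png"
                    render_chart(result, spec.family, path=path)
                    paths.append(str(path))
            return paths

        manifest["figures"] = _figures()
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, default=str)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
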