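# Methods

## The monitored process

The unit of monitoring is a practice-quarter: n_t bone-scan-non-indicated
patients (Gleason < 8 and PSA ≤ 20 ng/mL), of whom x_t received a
non-indicated staging bone scan. The model throughout is independent
Bernoulli adherence failures at a quarter-level rate, so
x_t ~ Binomial(n_t, p_t). The in-control state is p_t = p0 = 0.059 and the
design out-of-control state p1 = 0.114 — the collaborative's observed
post- and pre-intervention non-indicated bone-scan rates — with n = 26
patients per quarter, the mean volume of such patients per practice.
Deterioration means a *rise* in the rate, so all charts default to
upper-sided monitoring; two-sided variants exist for the p-chart and EWMA.

Independence across patients and quarters is an assumption, not a finding:
real registries have case-mix drift, clustered ordering behaviour and
seasonal volume; none of that is modelled, and passing tests say nothing
about those features.

## The four charts

* **p-chart.** p̂_t against p0 ± L·√(p0(1−p0)/n_t); memoryless, signal on a
  strict limit crossing. Its per-quarter signal probability is a binomial
  tail, so its run lengths are exactly geometric — used as a closed-form
  oracle for the simulator.
* **Weighted binomial CUSUM.** Tabular (reset-at-zero) CUSUM with
  Bernoulli log-likelihood-ratio increments for the designed shift
  p0 → p1: event weight ln(p1/p0) = 0.6587, non-event weight
  ln((1−p1)/(1−p0)) = −0.0602. The decision statistic is one-sided with a
  zero floor; the *plotted* statistic is the unreset observed-minus-
  expected count Σ(x_i − n_i·p0) ("golf score relative to par"), which can
  go negative and is easier to read. This LR form is equivalent to the
  classical count CUSUM with reference value k = n·w⁻/(w⁺−w⁻) ≈ 2.18
  events/quarter, up to a positive rescaling.
* **Bernoulli CUSUM.** The same increments applied patient-by-patient in
  (quarter, patient) order, with the floor applied after every patient and
  the alarm mapped to the quarter containing the alarming patient
  (ceil(i/26)). With one patient per period it coincides with the
  weighted binomial CUSUM exactly (property-tested).
* **EWMA.** Z_t = λ·p̂_t + (1−λ)·Z_{t−1}, Z_0 = p0 (no head start),
  λ = 0.2 by default — the conventional choice for detecting moderate
  sustained shifts. Limits use the exact time-varying variance
  p0(1−p0)·λ²·Σ_{i≤t}(1−λ)^{2(t−i)}/n_i, so early-quarter limits are
  tighter than the asymptotic band p0(1−p0)·λ/((2−λ)n); with λ = 1 the
  chart degenerates to the p-chart (property-tested).

Limit-crossing conventions: strict `>` for the continuous-statistic charts,
`≥ h` for the CUSUMs. Calibration absorbs the choice; calibrated limits are
placed in the open gaps of the empirical statistic lattice so the two
conventions select identical signal sets and floating-point ties cannot
occur.

## Calibration to a common false-signal budget

All four charts are standardized to the same in-control operating
characteristic: P(any signal within T = 20 in-control quarters) = 10 %.
Calibration is by simulation for every chart — uniform procedure, and the
binomial closed forms stay available as independent test oracles.

Because no chart's trajectory depends on its own limit, one set of R
simulated in-control trajectories yields, per run, the supremum of the
limit-comparable statistic; the false-signal probability at limit ℓ is the
tail frequency of these suprema. Under common random numbers this
empirical curve is *exactly* non-increasing in ℓ, so bisection converges;
the returned limit is the nearest-achievable one, i.e. the empirical-
quantile gap whose tail frequency is closest to the target, with both
flanking achievable probabilities reported. Default R = 100,000, giving a
Monte Carlo SE of ≈ 0.001 on the achieved probability.

The Bernoulli CUSUM is calibrated over the same horizon expressed in
patients (20 × 26 = 520), checking the decision statistic after every
patient.

**Discreteness.** At n = 26 the p-chart's achievable 20-quarter
false-signal probabilities jump 28.4 % → 6.74 % → 1.20 % as the implied
count threshold moves x ≥ 5 → 6 → 7; 10 % is unattainable. The nearest
achievable (6.74 %, threshold x ≥ 6) is selected and the gap disclosed in
the calibration report. This materially affects the p-chart's
out-of-control ARL: with x ≥ 6 the exact value is
1/P(Bin(26, 0.114) ≥ 6) = 14.7 quarters, and no limit consistent with this
calibration protocol produces an intermediate value (the next lattice point
gives 43.1). The CUSUM/EWMA statistic lattices are fine enough that their
achieved probabilities sit within ~0.1 pp of the target.

If a supplied bracket cannot reach the target the calibrator distinguishes
a mis-placed bracket (error, with diagnostics at both ends) from a target
that no positive limit achieves (proceeds, nearest-achievable, disclosed) —
the latter arises e.g. for median-level targets of a discrete upper-sided
statistic.

## Run-length estimation

Out-of-control runs start at period 1 with the chart in its initial state
(S = 0, Z = p0) and the process already at the true rate — no in-control
burn-in, matching the calibrated-then-shifted design; a `burn_in_periods`
option exists for sensitivity analysis since a chart mid-stream behaves
slightly differently. ARL estimates use 10,000 replications by default,
censored at max_periods = 400 quarters; censored runs are counted at the
censoring point and the estimate is flagged when they exceed 0.1 % of
runs (at the design rates censoring never occurs; sweeps near p0 use a
larger max_periods). Rate sweeps give every (chart, rate) cell its own
substream spawned from one base seed.

Pairwise chart comparisons use the two-sided Mann–Whitney U test on the
run-length samples — run-length distributions are strongly right-skewed,
so a rank test is the primary instrument — with Welch's t on log run
lengths as a secondary. Identical constant samples return p = 1 by
convention.

**A structural finding worth knowing:** at an equal achieved false-signal
budget the quarterly (weighted binomial) CUSUM slightly *outperforms* the
patient-by-patient Bernoulli CUSUM in quarter units (≈ 6.3 vs ≈ 6.6
quarters at 11.4 %). The per-patient chart spends part of its false-signal
budget on within-quarter crossings, but the quarter-ceiling alarm mapping
discards the sub-quarter timing advantage those crossings buy, so its
calibrated decision interval must be higher. The difference is small but
statistically unambiguous at 10,000 runs.

## Synthetic registry

The generator emulates the registry the cohort logic expects: per practice
and quarter it draws the non-indicated volume (exactly 26 under the
default `fixed` model, Poisson(26) optionally), an indicated volume
matching `indicated_fraction` (default 4983/23 672 ≈ 0.2105,
back-computed from the published cohort composition), scan events at the
quarter's active rate (baseline 5.9 %, change points applied from their
quarter onward) or at `indicated_scan_rate` (≈ 0.8116), and covariates
drawn *conditionally on the pre-assigned class* — Gleason from {6,…,10},
PSA log-normal, truncated so the indication classifier reproduces the
class exactly. Only the class matters downstream; the marginal covariate
distributions are not calibrated to any real population. Dates are placed
so no record trips an exclusion rule unless `exclusion_rate > 0`
deliberately injects exclusions (one of the three reasons, uniformly).

Randomness uses named substreams (volumes, classes, events, covariates,
dates, exclusions) spawned from the single seed; event draws are ordered
by (quarter, patient), so quarter-level binomial counts and patient-level
Bernoulli streams agree in distribution, and identical configs and seeds
reproduce byte-identical output.

## Cohort conventions

* Cohort entry date = the earlier of diagnosis date and first-encounter
  date when both exist, otherwise whichever exists.
* "Lack of imaging recorded less than 30 days after entry" is strict:
  day 30 is retained.
* A record whose only bone-scan order is external is excluded; missing
  imaging status (or a malformed row) is excluded; missing Gleason or PSA
  makes the indication unclassifiable and is excluded and tallied.
  Precedence when several apply: missing status → early no-imaging →
  external-only → unclassifiable.
* Aggregation quarter = calendar quarter of the entry date (switchable to
  diagnosis or encounter quarter); quarter indices are shared across
  practices; empty quarters are emitted with n_t = 0 and skipped by the
  charts.

## Problem sizes and determinism

Default problem sizes — 100,000 calibration replications, 10,000 ARL
replications, 20-quarter horizon — run in seconds on one CPU thanks to the
vectorized kernels, and every public entry point is deterministic given
its seed; the pipeline derives all stage seeds from one master seed and
records them, with achieved-vs-target calibration values, in its manifest
and log.

## Known limitations

* The binomial/Bernoulli independence model ignores case-mix,
  within-practice correlation and volume trends; ARLs under real registry
  dynamics will differ.
* ARL comparisons are zero-state (shift at t = 0 with a fresh chart);
  steady-state ARLs, worst-case change-point timing and risk-adjusted
  (covariate-dependent) CUSUMs are out of scope.
* The p-chart's discreteness at small n makes its calibrated operating
  characteristic, and hence its ARL, sensitive to the discreteness policy;
  the nearest-achievable policy used here is one defensible choice and is
  always disclosed in the calibration report.
* Censored runs are counted at the censoring horizon, a small downward
  bias that is negligible below the 0.1 % flagging ceiling.
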