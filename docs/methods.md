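# Methods

This note documents how `cgmetrics` computes what it computes, the
parameter choices that matter, and where conventions had to be fixed
that the literature leaves open.

## Input model and preprocessing

A trace is an irregular series of (timestamp, glucose) pairs for one
subject, held in mg/dL (mmol/L inputs are converted with the single
constant 18.016 mg/dL per mmol/L — the molar mass of glucose divided by
ten).  Timestamps are wall-clock naive; no timezone or DST arithmetic
is performed, which matches the plain `YYYY-MM-DD HH:MM:SS` input
format.  Rows with unparseable timestamps or non-numeric glucose are
dropped and counted.

**Duplicates.**  Exports frequently repeat timestamps.  At most one
sample per timestamp is kept; when duplicated timestamps disagree in
value the *first occurrence in file order* is retained and a warning
logged.  First-kept is a package convention — any fixed tie-break would
do, but it must be deterministic.

**Gap detection.**  With expected interval Δ (default 5 min) and
tolerance τ (default 0.05), a consecutive pair of readings separated by
more than Δ(1+τ) delimits a missing period.  The tolerance is
interpreted as a *fraction* of the interval because typical configured
values (0.05) make no sense as literal minutes; `tolerance_unit:
minutes` restores the literal reading.  The expected number of missing
grid samples in a gap of length dt is round(dt/Δ) − 1.

**Reconstruction.**  The default policy evaluates a shape-preserving
piecewise cubic Hermite interpolant (PCHIP; Fritsch–Carlson derivative
limiting, via `scipy.interpolate.PchipInterpolator`) on the regular
grid anchored at the *first observation* (the anchor is a convention;
midnight anchoring would shift every grid point for subjects whose
monitoring starts mid-day).  Grid points within Δ·τ of an observation
take the observed value and are flagged `imputed=False`; everything
else is interpolated and flagged.  No extrapolation is ever performed
beyond the first/last observation.  PCHIP cannot overshoot: between two
observations of locally monotone data the interpolant stays inside the
bracketing values, which is why it is the standard choice for glucose
signals.  An optional cap `max_gap_min` (default: unlimited) excludes
longer gaps from the grid instead of filling them — multi-hour cubic
fills are clinically dubious — splitting the signal into segments.

The alternative policy (`missing_policy=remove`) keeps the observed
segments, each snapped to its own regular grid, and every lag- or
difference-based metric downstream refuses to difference across a
segment boundary.

**Coverage.**  CompletenessRate = 100 × observed / expected, with
expected = floor(span/Δ) + 1 over the first-to-last observation span
(nominal wear duration is unknown to the tool).  MonitoringDays counts
distinct calendar dates with ≥1 observation.

## Segmentation

Night is the half-open clock window [00:00, `end_of_night_hour`)
(default 6); day is the complement.  Only the *end* of the night is a
parameter — the start is fixed at midnight, matching the use of the
night window for fasting estimation.  Day/night and calendar-day splits
depend only on timestamps.

## Metric aggregation

Descriptive statistics (mean, median, SD with n−1, CV = 100·SD/mean,
quartiles, IQR) and the time-in-range family are computed per calendar
day — on the whole day and on its day/night subsets — and averaged,
unweighted, across qualifying days (`tir_aggregation="pooled"` computes
them once over all samples instead).  A *qualifying day* has observed
(non-imputed) completeness ≥70 % of the 288-sample day, a filter in
line with CGM consensus practice; without it, partial first/last days
would distort day-to-day statistics.  Day-to-day SDs (of per-day mean
glucose and per-day TIR) are sample SDs across qualifying days.
Imputed samples are *included* in all metric computations under the
interpolate policy — the metrics are defined on the reconstructed,
complete signal.  `sample_n` (whole/day/night) reports observed,
non-imputed sample counts.

Range boundaries are arranged as an exact partition: TIR [70, 180],
TITR [70, 140], TBR1 [54, 70), TBR2 (−∞, 54), TAR1 (180, 250],
TAR2 (250, ∞) mg/dL.  Published band labels overlap at the edges; a
partition must pick sides, and this one keeps TIR + TBR + TAR ≡ 100.

## Risk indices

- **GRI**: hypoglycemia component %(<54) + 0.8·%(54–70), hyperglycemia
  component %(>250) + 0.5·%(181–250], composite
  min(100, 3.0·hypo + 1.6·hyper).  Strata reuse the range partition.
- **LBGI/HBGI**: f(g) = 1.509((ln g)^1.084 − 5.381) for g in mg/dL,
  per-sample risk 10·f², LBGI the mean over all samples of the risk
  where f<0 (zero otherwise), HBGI mirror-image.  A sample contributes
  to at most one side.
- **GRADE**: per-sample score min(50, 425·(log₁₀ log₁₀ g_mmol + 0.16)²)
  with g_mmol = g/18.016; the summary is the *median* score, and the
  hypo/eu/hyper percentages split the summed score mass at 3.9 and
  7.8 mmol/L (boundaries inside the euglycemic band).  Readings at or
  below 1 mmol/L (18 mg/dL), where the double log is undefined, take
  the 50-point cap with a warning — real sensors never report there.

## Variability

- **CONGA(h)**: sample SD of G(t) − G(t−h) over all grid times with
  both samples in the same segment; lags 1, 2, 6, 24 h.
- **MAGE**: σ is the sample SD of the whole reconstructed signal.
  Turning points come from an alternating scan: track the running
  candidate extremum and commit it once the signal reverses from it by
  ≥σ, so adjacent retained extrema always differ by ≥σ and sub-σ
  wiggles are absorbed; the trailing candidate of the final run is
  appended.  MAGE is the mean |λ| over consecutive-extrema differences
  with |λ| ≥ σ, counting rises *and* falls (the symmetric variant, per
  the defining formula, rather than the first-direction-only variant).
  Whether sub-σ fluctuations are merged before or after thresholding
  differs between published implementations; the scan above is the
  package's documented, oracle-tested choice.
- **Mobility**: Var(successive differences)/Var(signal), both sample
  variances.
- **DTpM**: Σ|ΔG| divided by the monitoring span in minutes (summed
  kept-segment spans under the remove policy).

## Control indicators

- **GMI (%)** = 3.31 + 0.02392 × mean glucose (mg/dL), computed on the
  whole reconstructed signal's mean.
- **FGxP**: per night, the minimum over all 30-consecutive-minute
  windows of the window-mean; averaged across nights.  The window is
  30/Δ samples and must divide evenly (a 7-min grid is rejected with a
  clear error).  Nights without a full window are skipped.
- **Hypoglycemia episodes**: an episode opens at the first sample of a
  run of readings <70 mg/dL lasting ≥15 min and closes at the first
  sample of the next ≥70 run lasting ≥15 min (international consensus
  event definition: a brief recovery blip does not end the event).
  Episode records carry onset, offset, duration and nadir.

## Complexity

MCI is the sum over scales 1–7 of SampEn(m=2, r) of the coarse-grained
(non-overlapping block means) series, with r = 0.15 × SD of the
*original* series, held fixed across scales — the standard
multiscale-entropy convention; recomputing r per scale would conflate
amplitude shrinkage with complexity.  Sample entropy counts unordered
template pairs under the Chebyshev metric with self-matches excluded,
over the first n−m templates for both lengths.  A constant series
yields exactly 0 at every scale.  Any undefined scale (no matches)
makes the index missing rather than silently truncating the sum.  MCI
dominates runtime and can be disabled (`compute_mci=False`/`--no-mci`).

## Cross-metric analysis

R²(a,b) is the squared Pearson correlation of two metric columns across
subjects (equivalently the R² of either simple regression — hence
symmetric), with pairwise-complete handling of missing values and
exclusion of zero-variance metrics.  The default metric set is the
whole-signal panel (day/night variants excluded).  The per-metric
*cumulative* off-diagonal R² ranks metrics by independence; the heatmap
export bins values into the tiers 0–0.2, 0.2–0.4, 0.4–0.6, 0.6–0.8,
≥0.8.  The circular-plot presentation of the most independent metrics
is replaced by a ranked table with each metric's closest partner.

## Synthetic data

The generator emulates the statistical structure of an insulin-treated
type-2-diabetes profile, not its physiology: basal level (default
140 mg/dL) + circadian sinusoid (20 mg/dL) + exponential-decay meal
pulses (60 mg/dL at 08:00/13:00/19:00, 90-min decay) + AR(1) noise
(stationary SD 10 mg/dL, φ = 0.7), clipped to the 40–400 mg/dL sensor
range, on a 5-min grid over 7 days.  AR(1) rather than white noise
gives Mobility, DTpM and MCI non-degenerate targets.  The degrader
removes samples strictly inside specified windows and injects
duplicated rows.  What passing tests on these fixtures do **not**
show: robustness to sensor artifacts (spikes, compression lows),
calibration drift, or vendor-specific export quirks — real data carry
all three.

## Numerical conventions

Sample (n−1) SDs and variances throughout; linear-interpolation
percentiles; metric values undefined on an input are NaN internally and
empty cells in the CSV (never sentinel numbers); floats are written at
12 significant digits so a read-back round trip is faithful.  Problem
sizes in the test suite (traces of ≤500 samples for oracle-equivalence
checks, n≈2000 for the multiscale-entropy checks, 20×7-day cohorts for
the end-to-end run) were chosen as the smallest sizes at which each
property is non-trivially exercised.

## Known limitations

- Night is fixed to start at midnight; shift-workers violate this.
- No artifact filtering beyond deduplication — outlier spikes propagate
  into MAGE, DTpM and entropy.
- PCHIP fills of very long gaps are smooth but not physiological; use
  `max_gap_min` or the remove policy when coverage is poor.
- The day-to-day SD requires ≥2 qualifying days and is sensitive to the
  70 % qualifying-day threshold for sparse traces.
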