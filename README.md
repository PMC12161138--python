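# cgmetrics

Post-hoc analytics for continuous glucose monitoring (CGM) data, for
diabetes researchers and clinical-trial analysts.  Raw sensor exports —
two-column CSV files of timestamp and glucose — are preprocessed
(duplicate removal, missing-period detection, shape-preserving cubic
reconstruction), then condensed into one row per subject covering the
standard clinical metric panel: descriptive statistics, the
time-in-range family, glycemic risk indices, variability measures,
control indicators and a multiscale complexity index, each with
day/night variants where clinically meaningful, plus day-to-day
variability.  A cohort-level analysis of the pairwise coefficients of
determination (R²) between metrics identifies which metrics carry
independent information.

## The methods in brief

- **Gap handling.** Consecutive readings further apart than
  `interval × (1 + tolerance)` delimit a missing period.  Gaps are
  filled on the expected grid by the monotonicity-preserving piecewise
  cubic Hermite interpolant (PCHIP, Fritsch–Carlson derivatives), which
  never overshoots the bracketing observations; alternatively missing
  periods are removed and metrics respect the segment boundaries.
- **Time in ranges.** TIR [70, 180] mg/dL, tight range [70, 140], below
  range (level 1 [54, 70), level 2 < 54), above range (level 1
  (180, 250], level 2 > 250), arranged as an exact partition so
  TIR + TBR + TAR ≡ 100 %.
- **Risk.** GRI = min(100, 3.0·GRIₕᵧₚₒ + 1.6·GRIₕᵧₚₑᵣ) with
  GRIₕᵧₚₒ = %(<54) + 0.8·%(54–70) and GRIₕᵧₚₑᵣ = %(>250) + 0.5·%(181–250);
  LBGI/HBGI from the log-symmetrized risk transform
  f(g) = 1.509·((ln g)^1.084 − 5.381); GRADE as the median of
  min(50, 425·(log₁₀ log₁₀ g_mmol + 0.16)²) with a hypo/eu/hyper
  decomposition of the score mass.
- **Variability.** CONGA (SD of lagged differences at 1/2/6/24 h);
  MAGE = mean |λ| over nadir↔peak excursions with |λ| ≥ σ, both
  directions, via an alternating turning-point scan; signal Mobility
  (variance of successive differences over signal variance); distance
  traveled per minute (Σ|ΔG| / span).
- **Control.** GMI (%) = 3.31 + 0.02392 × mean glucose [mg/dL]; a
  fasting glucose proxy (mean of the lowest 30 consecutive nighttime
  minutes, averaged across nights); hypoglycemia episodes (<70 mg/dL
  sustained ≥15 min, closed only after ≥15 min of recovery).
- **Complexity.** MCI = Σ over scales 1–7 of the sample entropy
  (m = 2, Chebyshev distance, r = 0.15 × SD) of the coarse-grained
  signal.

## Worked example

```bash
cgmetrics synth --subjects 5 --days 7 --seed 42 --out-dir fixtures
cgmetrics run fixtures --out metrics.csv
cgmetrics rsq metrics.csv --out rsq.csv
```

The `run` step prints `wrote 5 subject row(s) to metrics.csv`; a
selection of the panel (values in mg/dL, %, or unitless as appropriate):

```
               Mean     CV    TIR    TAR   GMI   MAGE  CONGA_1H    MCI    GRI
subject_000  178.75  11.71  54.81  45.19  7.59  40.61     23.79  12.46  36.27
subject_001  173.56  11.58  66.27  33.73  7.46  43.63     22.85  11.15  26.98
subject_002  189.02  11.81  35.37  64.63  7.83  45.72     26.71  13.12  52.50
subject_003  140.01  14.96  95.54   4.46  6.66  41.52     24.36  12.16   3.57
subject_004  153.78  14.73  87.65  12.35  6.99  47.45     28.10  13.28   9.88
```

Subject 003 spends 95.5 % of the week in range with an estimated
HbA1c-like GMI of 6.7 %, while subject 002's mean of 189 mg/dL pushes
two-thirds of its time above range and a GRI of 52.5 (higher = more
combined hypo/hyperglycemic exposure).  The `rsq` step then reports,
across subjects, which metrics are least explained by the rest (lowest
cumulative R²) together with each one's closest partner metric — on
this small demo cohort it prints, e.g.:

```
  MAGE             cumulative R^2 =   5.026   closest partner: CONGA_2H (R^2 = 0.766)
  D2d_mean         cumulative R^2 =   7.811   closest partner: CONGA_1H (R^2 = 0.876)
```

The same pipeline is available as a library (`cgmetrics.run_single`,
`run_batch`, `r_squared_matrix`, and the individual metric functions).

## Input contract

Two-column CSV: timestamp `YYYY-MM-DD HH:MM:SS` and glucose in mg/dL
(or mmol/L with `--convert`); header optional (auto-detected).  Vendor
exports (Dexcom Clarity, LibreView) must be reduced to this form first.

See `docs/methods.md` for the full description of the model choices,
parameters, and limitations.
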