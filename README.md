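# tqtkit

Design, simulation and analysis toolkit for thorough QT/QTc (TQT) crossover
trials that replicate the placebo period.

A TQT trial decides whether a drug prolongs the heart-rate-corrected QT
interval by more than the 10 ms threshold of regulatory concern.  The
five-period crossover studied here administers placebo twice (plus a
therapeutic dose, a supratherapeutic dose and a moxifloxacin-style positive
control): pooling two placebo periods lowers the variance of every
active-vs-placebo contrast from `2*sigma^2/n` to `1.5*sigma^2/n`, which cuts
the required sample size by 25% (30 vs 40 randomised subjects at the standard
assumptions) while keeping per-dose power at ~95% and overall power at ~90%.

## What is in the box

| module               | contents |
| -------------------- | -------- |
| `tqtkit.design`      | Williams square generation (carryover balance), placebo-symbol assignment under the placement constraint, blocked randomisation, session accounting, analytic power and the sample-size calculator |
| `tqtkit.synthetic`   | full synthetic trials (beat-level ECG + PK concentration tables, triplicate/measurement schedule, dropout) and fast endpoint-level datasets calibrated to the 14 ms endpoint SD |
| `tqtkit.ecg`         | beat/replicate averaging, period baselines, heart-rate corrections QTcB/QTcF/QTcI/QTcN (`QTc = QT*(1000/RR)^delta`, exponents fixed or fitted by linear mixed model on the log scale) |
| `tqtkit.analysis`    | change-from-baseline endpoints, primary mixed ANCOVA with pooled double placebo, per-timepoint contrasts, assay-sensitivity superiority test, categorical/outlier incidence, notable HR/PR/QRS changes, sex subgroup and the sensitivity analyses (single placebo, global baseline, one-step QT) |
| `tqtkit.nca`         | noncompartmental PK: Cmax/tmax, AUC(0-tz) with linear-up/log-down trapezoids, geometric mean / CV summaries |
| `tqtkit.exposure`    | concentration-QTc linear mixed exposure-response fits and prediction at the geometric-mean Cmax |
| `tqtkit.power`       | Monte Carlo verification: per-dose/overall power, type-I error at the margin, SE inflation of single- vs double-placebo analyses, sample-size reduction |
| `tqtkit.pipeline` / `tqtkit.cli` / `tqtkit.io` | end-to-end reproducible pipeline, input validation, `tqt` command line |

## Command line

```bash
tqt samplesize                          # 30 randomised (27 completers + 3), 25% reduction
tqt design --subjects 30 --seed 1       # Williams design + blocked allocation
tqt power --design double --n 27 --reps 10000 --seed 1
tqt simulate --seed 1 --out data/       # synthetic ECG + PK CSVs
tqt correct --ecg data/ecg.csv --method population --out tp.csv
tqt analyze --timepoints tp.csv --endpoint window_1_4h
tqt nca --pk data/pk.csv --lloq 1.11
tqt er --timepoints tp.csv --pk data/pk.csv
tqt run --demo --seed 1 --out report/   # full pipeline, report bundle
```

`tqt run` emits the report tables (primary contrasts with 90% CIs,
per-timepoint contrasts, categorical incidence, NCA summary, exposure-response
fits, single-vs-double placebo SE comparison) as CSV plus a machine-readable
`results.json`; re-running with the same config and seed reproduces every
output byte for byte.

## Conventions

All QT/RR/PR/QRS values are in ms, times in hours relative to dosing
(pre-dose negative), concentrations in nmol/L.  CSVs are UTF-8 with a header
row and `.` decimals.  Missing data are never imputed: subjects/periods
without a baseline are excluded from the affected analysis and counted.
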