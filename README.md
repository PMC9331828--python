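# fcs-screen

Screening pipeline for familial chylomicronemia syndrome (FCS) on
longitudinal hospital records. The package implements:

- **records_io** — long-format CSV readers/writers for lab measurements,
  ICD-10 diagnosis events and a patient roster, with per-file rejection
  accounting and a YAML/JSON criteria configuration;
- **fcs_scoring** — the expert-panel FCS score: per-criterion point
  breakdown (sustained/peak/low triglycerides, secondary factors,
  pancreatitis, recurrent abdominal pain, FCHL history, treatment
  non-response, onset age) with totals in [-5, 15] and a three-way
  category (likely / unlikely / highly unlikely);
- **rapid_cascade** — the rapid score-estimation cascade: six sequential
  population filters (all → sustained TG & never low → no secondary factor
  → peak TG → onset < 40 → pancreatitis) with per-stage counts and rates;
- **cohort_statistics** — prevalence rates at mixed scales (%, ‰, ‱,
  per-100,000 "pcm", per-million "ppm") with half-up rounding, and
  sex-stratified cumulative/disjoint score-distribution tables;
- **synthetic_cohort** — a seeded generator of cohorts with planted FCS,
  MFCS-like and background strata plus ground-truth labels;
- **ml_benchmark** — per-patient feature aggregation (highest / lowest /
  average / fluctuation / count per analyte, ICD prefix flags), repeated
  train/test evaluation of gradient boosting, AdaBoost, SVM and a ReLU
  network, rank-based AUC, 0-100 depth-weighted feature importance and
  decision-cut extraction from the first boosted trees.

## CLI

```sh
# generate a synthetic cohort (labs.csv, diagnoses.csv, roster.csv, truth.csv)
fcs-screen simulate --n 5000 --fcs-fraction 0.002 --seed 0 --out-dir cohort/

# per-patient score breakdown
fcs-screen score --labs cohort/labs.csv --diagnoses cohort/diagnoses.csv \
    --roster cohort/roster.csv --out scores.csv

# rapid estimation cascade
fcs-screen cascade --labs cohort/labs.csv --diagnoses cohort/diagnoses.csv \
    --roster cohort/roster.csv --out cascade.csv

# score-distribution table (add --disjoint for disjoint bins)
fcs-screen stats --scores scores.csv --roster cohort/roster.csv --out dist.csv

# a single formatted rate
fcs-screen prevalence --count 26 --population 1342124 --scale ppm --decimals 1

# classifier benchmark (summary.csv, importance.csv, cuts.csv)
fcs-screen ml-benchmark --cohort-dir cohort/ --experiments 30 --out-dir ml/
```

All commands accept `--config criteria.yaml` to override any scoring
threshold or ICD-10 prefix set (unknown keys are rejected).

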