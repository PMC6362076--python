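# lofscreen

Unsupervised anomaly screening for multidimensional behavioral cohort tables,
built around the local outlier factor (LOF).

## The problem

Early neurodevelopmental screening increasingly collects several parent-report
instruments at once — a reciprocal-social-behavior total, repetitive-behavior
subscales, an expressive vocabulary count — together with age and sex, for
community samples of toddlers. No single scale separates children at risk from
typical development, and diagnostic labels are not available at screening age.
An unsupervised alternative is to ask which children are *anomalous* across
all dimensions jointly: which records sit in low-density regions of the
feature space.

`lofscreen` implements that analysis as a reusable, tested pipeline:

1. **LOF scoring** (from first principles). For each subject *p* with
   tie-inclusive k-nearest neighborhood *N_k(p)*:

   - reach_k(p, o) = max(k-distance(o), d(p, o))
   - lrd(p) = |N_k(p)| / Σ_{o∈N_k(p)} reach_k(p, o)
   - LOF(p) = ( Σ_{o∈N_k(p)} lrd(o) / lrd(p) ) / |N_k(p)|

   Scores near 1 mean the subject is as dense as its neighbors; scores well
   above 1 mean relative isolation. Features are z-scored before distance
   computation (the instruments live on incommensurate scales); the default
   neighborhood size is k = 20.
2. **Thresholding.** Anomalies are the subjects strictly above the
   linear-interpolation 95th-percentile score, or above a data-driven
   percentile found by scanning the score density for the point where the
   central "bump" gives way to a flat low-density tail.
3. **Validation.** Omit-and-recompute (drop the flagged subjects, re-score,
   count fresh exceedances of the original cutoff) and half-sample resampling
   (re-score many random 50% subsamples; report anomaly overlap, score
   correlation, and the fraction of half-sample anomalies above a relaxed
   full-sample cutoff).
4. **Synthetic cohorts.** Because real screening data of this kind is not
   public, a seeded generator produces labeled stand-in cohorts: a typical
   majority with correlated scales and age-linked vocabulary, plus a small
   diffuse atypical subpopulation (right-skewed severity, age-decoupled
   vocabulary) for blind evaluation of recall and precision.

## Worked example

```python
from lofscreen import CohortSpec, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort_spec=CohortSpec(n_subjects=1570, seed=42),
    k=20, percentile=95.0,
    stability_reps=1000, stability_seed=7,
    out_dir="demo_run",
)
report = run_pipeline(config)
print(report.threshold["n_flagged"], report.removal_check["n_new"])
print(report.half_sample)
print(report.recovery)
```

On this cohort (1570 subjects, 5% atypical at a 3-SD shift) the run prints:

- `79 3` — 79 of 1570 subjects (5.03%) score strictly above the
  95th-percentile cutoff 1.464; after omitting them and re-scoring, only 3
  subjects newly exceed the original cutoff, so the flagged set is a real
  low-density tail rather than an artifact of the percentile construction.
- half-sample block: over 1000 half-size subsamples, on average 96.9% of
  within-half anomalies are also full-sample anomalies, the half/full score
  correlation is 0.940, and 99.0% of half-sample anomalies have a full-sample
  score of at least the relaxed secondary cutoff 1.269 — the scores barely
  depend on sample size.
- recovery block: against the generator's hidden labels the flagged set has
  precision = recall = 0.911 (72 of 79 atypical children found, 7 false
  positives).
- The flagged 5.03% sits between the ~13% prevalence of developmental
  disabilities and the 1.5–2% prevalence of ASD, reported as context in the
  prevalence block.

The same stages are available individually from the shell:

```bash
lofscreen simulate --config spec.json --out cohort.csv --labels labels.csv
lofscreen score --in cohort.csv --k 20 --out scores.csv
lofscreen threshold --scores scores.csv --percentile 95
lofscreen stability --in cohort.csv --k 20 --reps 1000 --seed 7 --out report.json
lofscreen evaluate --flagged flagged.csv --labels labels.csv
```

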