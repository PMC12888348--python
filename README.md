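# bicarbkin

Blood bicarbonate kinetics, test–retest reliability and gastrointestinal
(GI) symptom analysis for extracellular-buffering supplementation studies.

Alkalising supplements such as sodium citrate raise blood bicarbonate
([HCO₃⁻]), and an increase of +5 to +6 mmol·L⁻¹ above baseline is the
benchmark commonly used for a likely ergogenic effect. Athletes need to
know *when* that window occurs and *how repeatable* it is within an
individual: if the timing metrics are unreliable, a fixed
ingestion-to-performance interval will mistime peak alkalosis. This
package implements the full analysis for a two-visit repeated-measures
design with sparse capillary sampling (0, 30, …, 240 min), for sport and
exercise scientists running such trials:

- **Interpolation** — shape-preserving piecewise cubic Hermite
  interpolation (pchip, Fritsch–Carlson derivative limiting) of each
  subject-visit series onto a 1-minute grid; no overshoot between knots,
  no extrapolation.
- **Kinetic metrics** — baseline (observed value at 0 min), absolute peak
  concentration C_max, time to peak TTP (earliest minute of a plateau of
  equal maxima), earliest minutes meeting baseline +5 and +6 mmol·L⁻¹
  (missing if never reached), and total AUC by trapezoidal integration
  over 0–240 min.
- **Reliability** — for each metric: ICC(2,1) (two-way random effects,
  absolute agreement, single measurement) with the McGraw–Wong F-based
  95% CI; typical error TE = SD(Δ)/√2 with a χ²-scaled CI; CV% =
  100·TE/grand mean; paired t or Wilcoxon comparison gated by
  Shapiro–Wilk; listwise deletion with exclusion counts; interpretation
  bands (<0.50 poor, 0.50–0.74 moderate, 0.75–0.89 good, ≥0.90 excellent).
- **Threshold simulation** — per 30-min time point, the change from
  baseline pooled over subjects and visits is modelled as Normal(μ, σ);
  100,000 Monte Carlo draws per (time, threshold) cell estimate
  P(Δ > +5) and P(Δ > +6), flagged against a predefined 80% cutoff.
- **GI scoring** — 12-item Likert questionnaire (1–10): subtract-1
  correction, per-timepoint composite (0–108), per-visit totals, symptom
  prevalence (reported = corrected rating > 0 at any timepoint),
  Yates-corrected χ² between visits, and reliability of overall burden.
- **Synthetic cohorts** — Bateman-style absorption–elimination truth
  curves C(t) = B + Δpeak·g(t; τ) with controllable between-subject /
  within-subject variance components and measurement noise, so every
  stage is testable against closed-form ground truth.

## Worked example

Run the numbered analysis scripts in order (each writes tables under
`results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_kinetic_metrics.py
python analysis/03_reliability.py
python analysis/04_threshold_probability.py
python analysis/05_gi_symptoms.py
python analysis/06_figures.py
```

`03_reliability.py` prints, for the default synthetic cohort (seed 42):

```
metric         n  excl     ICC       TE     CV%  band
baseline      12     0    0.70     0.99     4.0  moderate
cmax          12     0    0.45     2.22     6.5  poor
ttp_min       12     0    0.04    46.53    31.3  poor
t_plus5       10     2    0.91     8.61    20.5  excellent
t_plus6        9     3    0.71    13.75    29.1  moderate
auc           12     0    0.48   425.35     5.6  poor
```

Read: concentration-anchored metrics (baseline, with TE ≈ 1 mmol·L⁻¹ and
CV 4%) are far more repeatable between visits than timing metrics — TTP
has an ICC near 0 and a typical error of ~47 min, so an individual's
time-of-peak measured once says little about their next visit. Two of 12
subjects never reached +5 mmol·L⁻¹ in one of their visits and are
excluded listwise from that metric's reliability row (`excl`).

`04_threshold_probability.py` prints the exceedance table:

```
 time_min  P(+5 mmol/L) %  P(+6 mmol/L) %
     30.0            39.4            23.1
     60.0            73.5            61.1
     90.0            83.4            73.9
    120.0            88.1            80.2
    ...
+5 mmol/L crosses the 80% cutoff from 90 min onward
```

i.e. for this cohort the majority of individuals are expected to be at or
above the +5 mmol·L⁻¹ ergogenic benchmark from 90 minutes post-ingestion.

The same pipeline runs on real data from a long-format CSV
(`subject,visit,time_min,hco3`; column names remappable) via the CLI:

```bash
bicarbkin run cohort.csv --gi-csv gi.csv --out run_out --seed 1
```

## Layout

- `src/bicarbkin/` — library: `data_io`, `synth`, `interp`, `kinetics`,
  `reliability`, `threshold_sim`, `gi`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property and end-to-end oracle tests
- `docs/methods.md` — models, parameter choices, numerical decisions and
  limitations
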