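# Methods

## Study design the package models

A two-visit repeated-measures supplementation trial: each participant
ingests an alkalising dose (nominally 0.5 g sodium citrate per kg body
mass), capillary blood [HCO₃⁻] (mmol·L⁻¹) is sampled at 0, 30, …, 240
minutes (nine samples per visit), and a 12-item GI symptom questionnaire
(Likert 1–10) is administered at the same timepoints. The analysis asks
two questions: what are the kinetics of the induced alkalosis, and how
repeatable are they within an individual across visits?

## Interpolation

Sparse knots are interpolated onto a 1-minute grid with the monotone
piecewise cubic Hermite scheme of Fritsch and Carlson. Knot derivatives
are the interval-length-weighted harmonic mean of adjacent secant slopes,

d_k = (w₁ + w₂) / (w₁/Δ_{k−1} + w₂/Δ_k),  w₁ = 2h_k + h_{k−1}, w₂ = h_k + 2h_{k−1},

set to zero at local extrema (sign change or zero secant); the ends use
the shape-preserving one-sided three-point formula, zeroed when it
opposes the boundary secant and capped at three times it when the data
turn. Evaluation uses the Hermite basis in incremental form
(y_left + h01·Δy + h·(h10·d_left + h11·d_right)), which is exact at knots
and for constant data. Consequences: the interpolant is C¹, passes
through every knot, and is monotone on any interval whose knot values are
monotone — no overshoot between samples, which keeps derived peaks and
threshold crossings physiologically plausible. Extrapolation beyond the
observed span is refused rather than guessed. The implementation is
validated against an independent reference pchip to 1e−8 on random
monotone and non-monotone knot sets.

## Kinetic metrics

All six metrics are read from the cached 1-minute grid (0–240 inclusive):

- **baseline** — the observed t = 0 value (identical to the grid value by
  the knot property);
- **C_max, TTP** — global maximum over all 241 grid values; TTP is the
  earliest minute attaining it, using exact float equality for the
  plateau test (a tolerance knob exists, default 0, because the grid is
  the output of a deterministic interpolant, not a measurement);
  endpoints are eligible peaks;
- **time to +5 / +6** — earliest grid minute whose value meets or exceeds
  baseline + δ; never reached ⇒ recorded as missing (not 0, not 240),
  and handled downstream by listwise deletion;
- **AUC** — trapezoid rule over the 240 unit-width intervals; the total
  area (not incremental above baseline), so a flat 24 mmol·L⁻¹ profile
  scores 5760 mmol·min·L⁻¹.

## Reliability battery

For n complete subject pairs over k = 2 visits:

- **ICC(2,1)** (two-way random effects, absolute agreement, single
  measurement): from the two-way ANOVA mean squares (subjects MS_R,
  visits MS_C, error MS_E),
  ICC = (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)).
  The 95% CI uses the McGraw–Wong F-based formulas with Satterthwaite
  degrees of freedom. Negative estimates are reported as computed.
  Zero total variance raises an "undefined" error — all-identical data
  carry no information about agreement and must not masquerade as
  ICC = 1. When the error variance is exactly zero but subjects differ,
  the Satterthwaite df degenerates and the CI collapses to the point
  estimate.
- **Typical error** TE = SD(visit₂ − visit₁)/√2 (the standard
  sports-science definition), CI from χ² limits on the difference
  variance with df = n − 1.
- **CV%** = 100·TE / grand mean of all 2n observations, CI scaled from
  the TE CI by the same mean. This raw-scale ratio (rather than the
  log-transform method) is used because it is consistent with TE being
  reported in measurement units; the χ²-scaled CI is asymmetric about the
  point estimate, as expected for a variance-derived quantity.
- **Paired comparison**: Shapiro–Wilk on the differences gates a paired
  t-test (p > α) versus a Wilcoxon signed-rank test. All-zero differences
  short-circuit to p = 1 with a warning; constant nonzero differences are
  a zero-variance degenerate case reported as such.
- **Bands**: <0.50 poor, 0.50–0.74 moderate, 0.75–0.89 good, ≥0.90
  excellent; negative ICC ⇒ poor.

Listwise deletion: a subject missing a metric in either visit is excluded
from that metric's pairs and counted, so n_pairs + n_excluded always
equals the cohort size.

## Threshold-exceedance simulation

For each post-baseline schedule time, the change from baseline is pooled
over all subjects and both visits (a per-visit restriction is available
for sensitivity analysis) and modelled as Normal(μ, σ) with the n−1
denominator for σ. Exceedance probability is estimated by 100,000 Monte
Carlo draws per (time, threshold) cell; "exceeds" is strict >, a choice
that is immaterial for continuous normals but fixed for reproducibility.
σ = 0 returns the exact indicator of μ > threshold. Each cell draws from
its own substream seeded by (run seed, time, threshold), so adding a
threshold or time point never perturbs other cells; time points are
simulated independently (no covariance across time is modelled). The
estimator is validated against the analytic normal tail 1 − Φ((T−μ)/σ)
within 4·√(p(1−p)/n) across random (μ, σ, T) triples. The predefined 80%
cutoff flags cells where P ≥ 0.80, equivalently μ ≥ T + z₀.₈·σ.

## GI scoring

Raw ratings are corrected by subtracting 1 (0–9 scale; raw 1 is anchored
"no problem at all"). The per-timepoint composite is the sum of the 12
corrected ratings, bounded by 108; the per-visit total sums composites
over the visit's timepoints and therefore lives on its natural,
unbounded-by-108 scale (both quantities are exposed explicitly). A
symptom is "reported" when its corrected rating exceeds 0 at any
timepoint of a visit. Prevalence differences between visits use 2×2 χ²
tests with Yates continuity correction by default (small cohorts make the
uncorrected statistic anti-conservative; toggleable); empty margins
(symptom reported by everyone or no one in both visits) return χ² = 0,
p = 1 directly, and expected cell counts below 1 are flagged rather than
suppressed. Overall-burden reliability delegates the visit totals to the
reliability battery.

## Synthetic cohort generator

Each subject-visit's truth curve is the Bateman absorption–elimination
form C(t) = B + Δpeak·g(t), g(t) = (e^{−k_e t} − e^{−k_a t})/norm,
normalised so g(0) = 0 and g(τ) = 1, with k_a = r·k_e and
k_e = ln(r)/(τ(r−1)) so the maximum falls exactly at τ. Defaults emulate
a 0.5 g·kg⁻¹ citrate cohort: n = 12 subjects × 2 visits, schedule 0–240
by 30; baseline B ~ Normal(24.6, 1.4²); peak increment
Δpeak ~ Normal(8.6, 1.8²) (a ~33 mmol·L⁻¹ absolute peak over a
24.6 baseline; between-subject SD chosen so the absolute peak SD is
≈ 2.3 when combined with baseline spread); time of peak
τ ~ Normal(150, 50²) truncated to (0, 240] by rejection (redraws consume
the seeded stream); shape ratio r = 8 (slow elimination produces the long
post-peak plateau typical of citrate).

Visit-level deviations and noise control the *true* test–retest
reliability. No published variance decomposition exists for these
parameters, so the within-subject SDs are the package's own choices,
picked once to sit in the range that the reliability literature's typical
errors imply for this design: baseline 0.9 mmol·L⁻¹, peak increment
1.5 mmol·L⁻¹, time of peak 45 min, plus iid measurement noise
0.5 mmol·L⁻¹ (point-of-care analyser scale). With components σ_b
(between) and σ_w (within, including noise), generated metrics have
population ICC σ_b²/(σ_b²+σ_w²), which the reliability module recovers in
simulation — the core parameter-recovery test.

Degenerate draws: negative peak increments clamp to 0 (a non-responder);
noisy observations below 0.1 mmol·L⁻¹ clamp to that floor with a logged
warning (clamping preserves determinism where resampling would not).
Closed-form truth metrics (peak by construction, threshold crossings by
Brent root-finding on the monotone rising limb, AUC by adaptive
quadrature) provide the oracle for pipeline recovery tests.

What the generator does *not* emulate: circadian or dietary drift in
baseline, covariance between Δpeak and τ, autocorrelated measurement
error along a visit, right-censoring of peaks beyond 240 min, or any
dose–response structure. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated variance model, not
robustness to those real-data features.

### Sampling-resolution limits

With 30-minute knots, a peak falling between samples is only localisable
to within the knot interval: in noiseless recovery tests the interpolated
TTP deviates from the true τ by up to ~15 min (bounded by the knot
spacing), C_max is underestimated by up to ~0.3% for τ ≥ 60 min, AUC is
accurate to ~0.2%, and threshold-crossing times to ~1–3 min. Curves
peaking before 60 min are undersampled around the peak and only their AUC
is meaningfully recoverable. These are properties of the sampling design,
not of the implementation, and they mirror why timing metrics show poor
test–retest reliability in practice.

## Problem sizes and determinism

Simulation-based tests use 500 replicates for ICC/TE recovery (n = 50 and
n = 12 subjects respectively), 1000 random knot sets / profiles for the
interpolation and scan oracles, and 100,000 Monte Carlo iterations per
exceedance check — sizes at which the binomial/limit bounds asserted are
comfortably non-flaky under the fixed seeds used. All randomness flows
through numpy Generators seeded explicitly; pipeline outputs contain no
timestamps, so a rerun with the same inputs, config and seed is
byte-identical.

## Known limitations

- The normal model for changes from baseline is an assumption; no
  empirical-CDF or bootstrap exceedance mode is provided.
- ICC confidence intervals rely on normal-theory F distributions; with
  n ≈ 12 they are wide and approximate.
- The CV confidence interval is scaled from the χ²-based TE interval on
  the raw scale; a log-scale CV is not implemented.
- Threshold times near the end of the window are effectively
  right-censored by the 240-min cutoff; they are recorded as missing, and
  listwise deletion shrinks (and potentially biases) the analysable
  subsample for those metrics.
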