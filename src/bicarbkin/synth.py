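"""Synthetic cohorts emulating post-ingestion blood bicarbonate kinetics.

Each subject-visit's true concentration curve is a Bateman-style
absorption-elimination form

    C(t) = B + Dpeak * g(t; tau, r),   g(t) = (e^{-ke t} - e^{-ka t}) / norm,

normalised so g(0) = 0 and max g = g(tau) = 1, with ka = r * ke and
ke = ln(r) / (tau * (r - 1)) so the curve peaks exactly at tau. A large
absorption/elimination ratio r gives the slow decline ("plateau") typical
of alkalising supplements. Subject-level parameters (baseline B, peak
increment Dpeak, time of peak tau) are drawn from between-subject normal
distributions; visit-level deviations from within-subject normals control
the true test-retest reliability; observations are the truth curve at the
sampling schedule plus iid Gaussian measurement noise. The generator is
fully deterministic given the seed, and the noiseless truth metrics are
available in closed form as an oracle for the measurement pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .data_io import BicarbSeries, ValidationError
from .kinetics import MISSING, KineticMetrics

logger = logging.getLogger("bicarbkin")

#: Floor applied to noisy observations; keeps concentrations physical.
CONC_FLOOR = 0.1


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults emulate a 12-subject two-visit citrate study.

    Between-subject SDs set the spread of true subject means; the *_sd_within
    values are visit-to-visit deviations of the true parameters (biological
    day-to-day variation) and, with measurement_noise_sd (analyser noise),
    control the cohort's true test-retest reliability. Units: mmol/L for
    concentrations, minutes for times.
    """

    n_subjects: int = 12
    n_visits: int = 2
    schedule: tuple[int, ...] = tuple(range(0, 241, 30))
    baseline_mean: float = 24.6
    baseline_sd_between: float = 1.4
    delta_peak_mean: float = 8.6
    delta_peak_sd_between: float = 1.8
    ttp_mean: float = 150.0
    ttp_sd_between: float = 50.0
    baseline_sd_within: float = 0.9
    delta_peak_sd_within: float = 1.5
    ttp_sd_within: float = 45.0
    measurement_noise_sd: float = 0.5
    ka_ke_ratio: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        sds = (
            self.baseline_sd_between, self.delta_peak_sd_between, self.ttp_sd_between,
            self.baseline_sd_within, self.delta_peak_sd_within, self.ttp_sd_within,
            self.measurement_noise_sd,
        )
        if any(s < 0 for s in sds):
            raise ValidationError("all SDs must be >= 0")
        if self.n_subjects < 2 or self.n_visits < 2:
            raise ValidationError("need >= 2 subjects and >= 2 visits")
        if len(self.schedule) < 3:
            raise ValidationError("schedule must have >= 3 points")
        if not 0 < self.ttp_mean <= max(self.schedule):
            raise ValidationError("ttp_mean must lie within the schedule span")
        if self.ka_ke_ratio <= 1:
            raise ValidationError("ka_ke_ratio must exceed 1")


@dataclass(frozen=True)
class TrueSubjectKinetics:
    """Ground-truth curve parameters for one subject-visit."""

    subject_id: str
    visit: int
    baseline: float
    delta_peak: float
    tau: float
    ka_ke_ratio: float = 8.0

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.delta_peak < 0 or self.tau <= 0:
            raise ValidationError("require baseline > 0, delta_peak >= 0, tau > 0")


def _rates(tau: float, ratio: float) -> tuple[float, float]:
    """Absorption/elimination rate constants placing the curve maximum at tau."""
    ke = math.log(ratio) / (tau * (ratio - 1.0))
    return ratio * ke, ke


def bateman(t, tau: float, ratio: float = 8.0):
    """Normalised rise-and-decline shape: g(0) = 0, max g = g(tau) = 1."""
    ka, ke = _rates(tau, ratio)
    t = np.asarray(t, dtype=float)
    norm = math.exp(-ke * tau) - math.exp(-ka * tau)
    return (np.exp(-ke * t) - np.exp(-ka * t)) / norm


def truth_curve(truth: TrueSubjectKinetics, t):
    """Noiseless concentration at time(s) t."""
    if truth.delta_peak == 0.0:
        return truth.baseline + np.zeros_like(np.asarray(t, dtype=float))
    return truth.baseline + truth.delta_peak * bateman(t, truth.tau, truth.ka_ke_ratio)


def series_from_truth(
    truth: TrueSubjectKinetics,
    schedule,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BicarbSeries:
    """Observe the truth curve at schedule times with iid Gaussian noise.

    Negative draws are clamped at the 0.1 mmol/L floor with a warning
    (clamping, unlike resampling, preserves the seeded stream).
    """
    obs = np.asarray(truth_curve(truth, schedule), dtype=float)
    if noise_sd > 0:
        if rng is None:
            raise ValidationError("noise_sd > 0 requires an rng")
        obs = obs + rng.normal(0.0, noise_sd, size=len(obs))
    if np.any(obs < CONC_FLOOR):
        logger.warning(
            "%s visit %d: %d observation(s) clamped at %.1f mmol/L",
            truth.subject_id, truth.visit, int(np.sum(obs < CONC_FLOOR)), CONC_FLOOR,
        )
        obs = np.maximum(obs, CONC_FLOOR)
    return BicarbSeries(
        subject_id=truth.subject_id,
        visit=truth.visit,
        times=tuple(float(t) for t in schedule),
        concentrations=tuple(float(c) for c in obs),
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sample Normal(mean, sd) into (lo, hi]; draws count toward the stream."""
    if sd == 0.0:
        return min(max(mean, math.nextafter(lo, hi)), hi)
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if lo < v <= hi:
            return v
    raise ValidationError(f"truncated normal ({mean}, {sd}) in ({lo}, {hi}] did not converge")


def sample_cohort(
    params: CohortParams,
) -> tuple[list[BicarbSeries], list[TrueSubjectKinetics]]:
    """Draw a full synthetic cohort plus its ground truth.

    Subject-level true parameters come from the between-subject normals;
    each visit adds within-subject normal deviations; time-of-peak draws
    outside (0, schedule max] are redrawn by rejection. Deterministic given
    params.rng_seed.
    """
    rng = np.random.default_rng(params.rng_seed)
    span = float(max(params.schedule))
    series: list[BicarbSeries] = []
    truths: list[TrueSubjectKinetics] = []
    width = len(str(params.n_subjects))
    for i in range(params.n_subjects):
        sid = f"S{i + 1:0{width}d}"
        b_i = rng.normal(params.baseline_mean, params.baseline_sd_between)
        d_i = rng.normal(params.delta_peak_mean, params.delta_peak_sd_between)
        tau_i = _truncated_normal(rng, params.ttp_mean, params.ttp_sd_between, 0.0, span)
        for v in range(1, params.n_visits + 1):
            b = b_i + (rng.normal(0.0, params.baseline_sd_within)
                       if params.baseline_sd_within > 0 else 0.0)
            d = d_i + (rng.normal(0.0, params.delta_peak_sd_within)
                       if params.delta_peak_sd_within > 0 else 0.0)
            tau = (_truncated_normal(rng, tau_i, params.ttp_sd_within, 0.0, span)
                   if params.ttp_sd_within > 0 else tau_i)
            truth = TrueSubjectKinetics(
                subject_id=sid, visit=v,
                baseline=max(b, CONC_FLOOR),
                delta_peak=max(d, 0.0),
                tau=tau,
                ka_ke_ratio=params.ka_ke_ratio,
            )
            truths.append(truth)
            series.append(
                series_from_truth(truth, params.schedule,
                                  params.measurement_noise_sd, rng)
            )
    return series, truths


def true_metrics(
    truth: TrueSubjectKinetics,
    grid_start: float = 0.0,
    grid_end: float = 240.0,
    thresholds: tuple[float, ...] = (5.0, 6.0),
) -> KineticMetrics:
    """Closed-form metrics of the noiseless truth curve (oracle for recovery tests).

    Threshold-crossing times are solved by root bisection on the monotone
    rising limb of g; AUC by adaptive quadrature of the continuous curve.
    """
    b, d, tau = truth.baseline, truth.delta_peak, truth.tau
    ttp = min(max(tau, grid_start), grid_end)
    if d == 0.0:
        cmax, ttp = b, grid_start
    else:
        cmax = float(truth_curve(truth, ttp))

    ttd: dict[float, float | None] = {}
    for thr in thresholds:
        if d <= 0 or d * float(bateman(ttp, tau, truth.ka_ke_ratio)) < thr:
            ttd[float(thr)] = MISSING
        else:
            f = lambda t: d * float(bateman(t, tau, truth.ka_ke_ratio)) - thr
            hi = min(tau, grid_end)
            ttd[float(thr)] = float(brentq(f, 1e-9, hi, xtol=1e-9))

    auc, _ = quad(lambda t: float(truth_curve(truth, t)), grid_start, grid_end, limit=200)
    return KineticMetrics(
        subject_id=truth.subject_id, visit=truth.visit,
        baseline=b, cmax=cmax, ttp_min=ttp, time_to_delta=ttd, auc=float(auc),
    )


def sodium_citrate_dose_g(body_mass_kg: float, dose_g_per_kg: float = 0.5) -> float:
    """Grams of sodium citrate for a relative dose (default 0.5 g per kg body mass)."""
    if body_mass_kg <= 0 or dose_g_per_kg <= 0:
        raise ValidationError("body mass and relative dose must be positive")
    return body_mass_kg * dose_g_per_kg


def sample_gi_cohort(
    n_subjects: int = 12,
    n_visits: int = 2,
    schedule: tuple[int, ...] = tuple(range(0, 241, 30)),
    rng_seed: int = 0,
):
    """Synthetic 12-item GI questionnaire responses with realistic prevalence.

    Lower-GI symptoms (urge to defecate, flatulence, bloating) are made
    common and the rest sporadic, with a subject-level severity effect so
    visit totals show moderate test-retest agreement.
    """
    from .data_io import SYMPTOMS, GIResponse

    base_p = {
        "urge_to_defecate": 0.35, "flatulence": 0.28, "bloating": 0.22,
        "nausea": 0.10, "intestinal_cramps": 0.08, "loose_stool": 0.10,
        "reflux": 0.05, "heartburn": 0.05, "upper_abdominal_cramps": 0.06,
        "vomiting": 0.01, "dizziness": 0.04, "headache": 0.05,
    }
    rng = np.random.default_rng(rng_seed)
    width = len(str(n_subjects))
    responses = []
    for i in range(n_subjects):
        sid = f"S{i + 1:0{width}d}"
        susceptibility = math.exp(rng.normal(0.0, 0.6))
        for v in range(1, n_visits + 1):
            for t in schedule:
                # symptoms cluster mid-window, after the dose hits the gut
                time_w = 0.3 + 0.7 * math.sin(math.pi * min(t, 240) / 240.0)
                ratings = {}
                for s in SYMPTOMS:
                    p = min(base_p[s] * susceptibility * time_w, 0.95)
                    if rng.random() < p:
                        ratings[s] = 2 + int(min(rng.exponential(1.5), 8.0))
                    else:
                        ratings[s] = 1
                responses.append(GIResponse(sid, v, int(t), ratings))
    return responses
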