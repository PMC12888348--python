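"""Test-retest reliability statistics for per-subject-visit metrics.

Implements the standard sports-science reliability battery for a
two-visit repeated-measures design:

* ICC(2,1) — intraclass correlation, two-way random-effects, absolute
  agreement, single measurement (Shrout & Fleiss), from the two-way ANOVA
  mean squares::

      ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

  with the F-based McGraw & Wong confidence interval. Negative ICCs are
  reported as computed, never truncated.
* Typical error TE = SD(visit2 - visit1) / sqrt(2) (Hopkins), with a
  chi-square interval on the difference variance (df = n - 1).
* CV% = 100 * TE / grand mean of all 2n observations, interval scaled from
  the TE interval by the same mean.
* Paired visit comparison: Shapiro-Wilk on the differences gates a paired
  t-test (normal) versus a Wilcoxon signed-rank test.

Subjects missing a metric in either visit are removed by listwise deletion
and counted, mirroring how unreached threshold times are handled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import RunConfig, ValidationError
from .kinetics import MISSING, KineticMetrics

logger = logging.getLogger("bicarbkin")

#: ICC interpretation bands (lower edge inclusive).
ICC_BANDS: tuple[tuple[float, str], ...] = (
    (0.90, "excellent"),
    (0.75, "good"),
    (0.50, "moderate"),
    (-math.inf, "poor"),
)


class ICCUndefinedError(ValueError):
    """Zero total variance: agreement is undefined (not the same as ICC = 1)."""


@dataclass(frozen=True)
class PairedMetric:
    """Complete visit-1/visit-2 value pairs for one metric, after listwise deletion."""

    name: str
    subjects: tuple[str, ...]
    visit1: tuple[float, ...]
    visit2: tuple[float, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (len(self.subjects) == len(self.visit1) == len(self.visit2)):
            raise ValidationError("subjects, visit1, visit2 must align")

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class ReliabilityReport:
    """Reliability summary for one metric (one table row)."""

    metric: str
    n_pairs: int
    n_excluded: int
    mean_v1: float
    sd_v1: float
    mean_v2: float
    sd_v2: float
    paired_p: float
    test_used: str
    icc: float
    icc_ci: tuple[float, float]
    te: float
    te_ci: tuple[float, float]
    cv_pct: float
    cv_ci: tuple[float, float]
    mean_diff: float
    diff_min: float
    diff_max: float
    icc_band: str
    insufficient: bool = False


def _anova_mean_squares(x1: np.ndarray, x2: np.ndarray):
    """Two-way ANOVA decomposition for n subjects x k=2 visits (no replication)."""
    data = np.column_stack([x1, x2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return n, k, ms_r, ms_c, ms_e, ss_total


def icc_absolute_agreement(
    visit1, visit2, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(2,1) with the McGraw-Wong 95% (or 1-alpha) confidence interval.

    Raises ICCUndefinedError when the data have zero total variance, where
    agreement is vacuous rather than perfect.
    """
    x1 = np.asarray(visit1, dtype=float)
    x2 = np.asarray(visit2, dtype=float)
    if len(x1) < 2 or len(x1) != len(x2):
        raise ValidationError("need >= 2 complete pairs")
    n, k, ms_r, ms_c, ms_e, ss_total = _anova_mean_squares(x1, x2)
    if ss_total == 0.0:
        raise ICCUndefinedError("all observations identical: ICC undefined")
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    icc = (ms_r - ms_e) / denom

    # McGraw & Wong (1996) interval for ICC(A,1) via Satterthwaite df
    with np.errstate(all="ignore"):
        vn = (k - 1) * (n - 1) * (k * icc * ms_c + n * (1 + (k - 1) * icc) * ms_e
                                  - k * icc * ms_e) ** 2
        vd = ((n - 1) * k**2 * icc**2 * ms_c**2
              + (n * (1 + (k - 1) * icc) - k * icc) ** 2 * ms_e**2)
        v = vn / vd if vd > 0 else math.nan
    if not math.isfinite(v) or v <= 0:
        return float(icc), float(icc), float(icc)
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (ms_r - f_u * ms_e) / (
        f_u * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r
    )
    hi = n * (f_l * ms_r - ms_e) / (
        k * ms_c + (k * n - k - n) * ms_e + n * f_l * ms_r
    )
    return float(icc), float(lo), float(hi)


def typical_error(visit1, visit2, alpha: float = 0.05) -> tuple[float, float, float]:
    """TE = SD(differences)/sqrt(2); chi-square CI on the variance with df = n-1."""
    x1 = np.asarray(visit1, dtype=float)
    x2 = np.asarray(visit2, dtype=float)
    if len(x1) < 2 or len(x1) != len(x2):
        raise ValidationError("need >= 2 complete pairs")
    d = x2 - x1
    n = len(d)
    sd_d = float(np.std(d, ddof=1))
    te = sd_d / math.sqrt(2.0)
    df = n - 1
    lo = sd_d * math.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df)) / math.sqrt(2.0)
    hi = sd_d * math.sqrt(df / stats.chi2.ppf(alpha / 2, df)) / math.sqrt(2.0)
    return te, lo, hi


def coefficient_of_variation(
    visit1, visit2, alpha: float = 0.05
) -> tuple[float, float, float]:
    """CV% = 100 * TE / grand mean of all 2n observations; CI scaled from the TE CI."""
    x1 = np.asarray(visit1, dtype=float)
    x2 = np.asarray(visit2, dtype=float)
    grand = float(np.concatenate([x1, x2]).mean())
    if grand <= 0:
        raise ValidationError("CV undefined for non-positive grand mean")
    te, lo, hi = typical_error(x1, x2, alpha)
    return 100.0 * te / grand, 100.0 * lo / grand, 100.0 * hi / grand


def classify_icc(icc: float) -> str:
    """Interpretation band: <0.50 poor, 0.50-0.74 moderate, 0.75-0.89 good, >=0.90 excellent."""
    for edge, band in ICC_BANDS:
        if icc >= edge:
            return band
    return "poor"


def paired_comparison(visit1, visit2, alpha: float = 0.05) -> tuple[float, str]:
    """Paired t-test or Wilcoxon signed-rank, gated by Shapiro-Wilk on the differences."""
    x1 = np.asarray(visit1, dtype=float)
    x2 = np.asarray(visit2, dtype=float)
    if len(x1) < 3:
        raise ValidationError("paired comparison needs >= 3 pairs")
    d = x2 - x1
    if np.all(d == 0.0):
        logger.warning("all paired differences are zero: degenerate comparison, p = 1")
        return 1.0, "degenerate"
    if np.ptp(d) == 0.0:
        # constant nonzero shift: zero variance, the shift is certain
        logger.warning("constant nonzero differences: zero-variance comparison")
        return 0.0, "degenerate"
    sw_p = stats.shapiro(d).pvalue
    if sw_p > alpha:
        return float(stats.ttest_rel(x2, x1).pvalue), "paired-t"
    return float(stats.wilcoxon(x2, x1).pvalue), "wilcoxon"


def pair_metric(
    metrics: list[KineticMetrics], field_name: str, threshold: float | None = None
) -> PairedMetric:
    """Assemble visit-1/visit-2 pairs for one metric with listwise deletion.

    field_name is a KineticMetrics attribute, or "time_to_delta" with a
    threshold key. Subjects missing the value in either visit are excluded
    and counted in n_excluded.
    """
    by_subject: dict[str, dict[int, float | None]] = {}
    for m in metrics:
        if field_name == "time_to_delta":
            val = m.time_to_delta.get(float(threshold), MISSING)
        else:
            val = getattr(m, field_name)
        by_subject.setdefault(m.subject_id, {})[m.visit] = val

    name = field_name if threshold is None else f"t_plus{threshold:g}"
    subjects, v1, v2 = [], [], []
    n_excluded = 0
    for sid in sorted(by_subject):
        vals = by_subject[sid]
        a, b = vals.get(1, MISSING), vals.get(2, MISSING)
        if a is MISSING or b is MISSING:
            n_excluded += 1
            logger.info("metric %s: subject %s excluded (listwise deletion)", name, sid)
            continue
        subjects.append(sid)
        v1.append(float(a))
        v2.append(float(b))
    return PairedMetric(name=name, subjects=tuple(subjects),
                        visit1=tuple(v1), visit2=tuple(v2), n_excluded=n_excluded)


def report_for(pairs: PairedMetric, alpha: float = 0.05) -> ReliabilityReport:
    """Full reliability report for one paired metric."""
    nan = math.nan
    if pairs.n_pairs < 2:
        return ReliabilityReport(
            metric=pairs.name, n_pairs=pairs.n_pairs, n_excluded=pairs.n_excluded,
            mean_v1=nan, sd_v1=nan, mean_v2=nan, sd_v2=nan, paired_p=nan,
            test_used="none", icc=nan, icc_ci=(nan, nan), te=nan, te_ci=(nan, nan),
            cv_pct=nan, cv_ci=(nan, nan), mean_diff=nan, diff_min=nan, diff_max=nan,
            icc_band="n/a", insufficient=True,
        )
    x1 = np.asarray(pairs.visit1)
    x2 = np.asarray(pairs.visit2)
    d = x2 - x1
    try:
        icc, icc_lo, icc_hi = icc_absolute_agreement(x1, x2, alpha)
        band = classify_icc(icc)
    except ICCUndefinedError:
        icc, icc_lo, icc_hi, band = nan, nan, nan, "n/a"
    te, te_lo, te_hi = typical_error(x1, x2, alpha)
    try:
        cv, cv_lo, cv_hi = coefficient_of_variation(x1, x2, alpha)
    except ValidationError:
        cv, cv_lo, cv_hi = nan, nan, nan
    try:
        p, test_used = paired_comparison(x1, x2, alpha)
    except ValidationError:
        p, test_used = nan, "none"
    return ReliabilityReport(
        metric=pairs.name, n_pairs=pairs.n_pairs, n_excluded=pairs.n_excluded,
        mean_v1=float(x1.mean()), sd_v1=float(np.std(x1, ddof=1)),
        mean_v2=float(x2.mean()), sd_v2=float(np.std(x2, ddof=1)),
        paired_p=p, test_used=test_used,
        icc=icc, icc_ci=(icc_lo, icc_hi),
        te=te, te_ci=(te_lo, te_hi),
        cv_pct=cv, cv_ci=(cv_lo, cv_hi),
        mean_diff=float(d.mean()), diff_min=float(d.min()), diff_max=float(d.max()),
        icc_band=band,
    )


def reliability_table(
    metrics: list[KineticMetrics], config: RunConfig | None = None
) -> list[ReliabilityReport]:
    """One reliability report per kinetic metric (baseline, cmax, ttp, thresholds, auc)."""
    config = config or RunConfig()
    specs: list[tuple[str, float | None]] = [
        ("baseline", None), ("cmax", None), ("ttp_min", None),
    ]
    specs += [("time_to_delta", float(t)) for t in config.thresholds]
    specs += [("auc", None)]
    return [report_for(pair_metric(metrics, f, thr), config.alpha) for f, thr in specs]


def reports_frame(reports: list[ReliabilityReport]):
    """Tabulate reliability reports, one row per metric."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append({
            "metric": r.metric, "n_pairs": r.n_pairs, "n_excluded": r.n_excluded,
            "mean_v1": r.mean_v1, "sd_v1": r.sd_v1,
            "mean_v2": r.mean_v2, "sd_v2": r.sd_v2,
            "p_value": r.paired_p, "test": r.test_used,
            "icc": r.icc, "icc_lo": r.icc_ci[0], "icc_hi": r.icc_ci[1],
            "te": r.te, "te_lo": r.te_ci[0], "te_hi": r.te_ci[1],
            "cv_pct": r.cv_pct, "cv_lo": r.cv_ci[0], "cv_hi": r.cv_ci[1],
            "mean_diff": r.mean_diff, "diff_min": r.diff_min, "diff_max": r.diff_max,
            "icc_band": r.icc_band,
        })
    return pd.DataFrame(rows)
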