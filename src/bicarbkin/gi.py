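"""Gastrointestinal symptom questionnaire scoring and reliability.

Raw Likert ratings (1 = no problem at all ... 10 = worst ever) are
corrected by subtracting 1 onto a 0-9 scale. The per-timepoint composite
is the sum of the 12 corrected ratings (0-108); the per-visit total sums
the composites over all timepoints in the visit (its natural maximum is
108 x n_timepoints). A symptom counts as *reported* by a participant in a
visit when its corrected rating exceeds 0 (raw >= 2) at any timepoint —
raw 1 is the "no problem at all" anchor and never counts. Between-visit
prevalence is compared per symptom with 2x2 chi-square tests (Yates
continuity correction by default, given small n); overall symptom burden
reliability delegates to the reliability module on visit totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import SYMPTOMS, GIResponse, ValidationError
from .reliability import PairedMetric, ReliabilityReport, report_for

logger = logging.getLogger("bicarbkin")


@dataclass(frozen=True)
class GICompositeRecord:
    """Corrected (0-9) ratings and their sum for one subject-visit-timepoint."""

    subject_id: str
    visit: int
    time_min: int
    corrected: Mapping[str, int]
    composite_timepoint: int

    def __post_init__(self) -> None:
        if not 0 <= self.composite_timepoint <= 108:
            raise ValidationError("per-timepoint composite must be in 0..108")


@dataclass(frozen=True)
class GIVisitSummary:
    """Per-visit totals and ever-reported flags for one subject."""

    subject_id: str
    visit: int
    total_score: int
    any_symptom: bool
    reported: Mapping[str, bool]


def correct_and_compose(responses: Sequence[GIResponse]) -> list[GICompositeRecord]:
    """Subtract-1 correction and per-timepoint composite sum for each response."""
    out = []
    for r in responses:
        corrected = {s: r.ratings[s] - 1 for s in SYMPTOMS}
        out.append(
            GICompositeRecord(
                subject_id=r.subject_id,
                visit=r.visit,
                time_min=r.time_min,
                corrected=corrected,
                composite_timepoint=sum(corrected.values()),
            )
        )
    return out


def visit_summaries(responses: Sequence[GIResponse]) -> list[GIVisitSummary]:
    """Aggregate composites to per-subject per-visit totals and ever-reported flags."""
    records = correct_and_compose(responses)
    keys = sorted({(rec.subject_id, rec.visit) for rec in records})
    out = []
    for sid, visit in keys:
        recs = [r for r in records if r.subject_id == sid and r.visit == visit]
        reported = {s: any(r.corrected[s] > 0 for r in recs) for s in SYMPTOMS}
        out.append(
            GIVisitSummary(
                subject_id=sid,
                visit=visit,
                total_score=sum(r.composite_timepoint for r in recs),
                any_symptom=any(reported.values()),
                reported=reported,
            )
        )
    return out


def symptom_prevalence(responses: Sequence[GIResponse], visit: int) -> dict[str, int]:
    """Participants reporting each symptom (corrected > 0) at any timepoint of a visit."""
    summaries = [s for s in visit_summaries(responses) if s.visit == visit]
    return {s: sum(summ.reported[s] for summ in summaries) for s in SYMPTOMS}


def compare_prevalence(
    visit1_counts: Mapping[str, int],
    visit2_counts: Mapping[str, int],
    n: int,
    continuity: bool = True,
) -> pd.DataFrame:
    """Per-symptom 2x2 chi-square (reported vs not, visit 1 vs visit 2).

    Yates continuity correction is applied by default (small samples make
    the uncorrected statistic anti-conservative). Cells with expected
    count < 1 are flagged low_count rather than suppressed.
    """
    rows = []
    for s in SYMPTOMS:
        a, b = int(visit1_counts.get(s, 0)), int(visit2_counts.get(s, 0))
        if not (0 <= a <= n and 0 <= b <= n):
            raise ValidationError(f"{s}: counts must lie in 0..{n}")
        table = np.array([[a, n - a], [b, n - b]], dtype=float)
        expected = stats.contingency.expected_freq(table)
        low = bool((expected < 1).any())
        if low:
            logger.warning("%s: expected cell count < 1; chi-square unreliable", s)
        if table.sum(axis=0).min() == 0.0:
            # a margin is empty (symptom reported by all or by none in both visits)
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
        rows.append({"symptom": s, "visit1": a, "visit2": b, "chi2": float(chi2),
                     "p_value": float(p), "low_count": low})
    return pd.DataFrame(rows)


def gi_reliability(
    summaries: Sequence[GIVisitSummary], alpha: float = 0.05
) -> ReliabilityReport:
    """Test-retest reliability of the per-visit total GI burden (delegated)."""
    by_subject: dict[str, dict[int, int]] = {}
    for s in summaries:
        by_subject.setdefault(s.subject_id, {})[s.visit] = s.total_score
    subjects, v1, v2 = [], [], []
    n_excluded = 0
    for sid in sorted(by_subject):
        vals = by_subject[sid]
        if 1 in vals and 2 in vals:
            subjects.append(sid)
            v1.append(float(vals[1]))
            v2.append(float(vals[2]))
        else:
            n_excluded += 1
    pairs = PairedMetric(
        name="gi_total", subjects=tuple(subjects),
        visit1=tuple(v1), visit2=tuple(v2), n_excluded=n_excluded,
    )
    return report_for(pairs, alpha)
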