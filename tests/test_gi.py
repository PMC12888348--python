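import math

import numpy as np
import pytest

from bicarbkin.data_io import SYMPTOMS, GIResponse, ValidationError
from bicarbkin.gi import (
    compare_prevalence,
    correct_and_compose,
    gi_reliability,
    symptom_prevalence,
    visit_summaries,
)


def _response(subject="S1", visit=1, time_min=0, **ratings):
    full = {s: 1 for s in SYMPTOMS}
    full.update(ratings)
    return GIResponse(subject, visit, time_min, full)


class TestCorrectAndCompose:
    def test_all_ones_composite_zero(self):
        rec = correct_and_compose([_response()])[0]
        assert rec.composite_timepoint == 0
        assert all(v == 0 for v in rec.corrected.values())

    def test_all_tens_composite_108(self):
        """Scale maximum: 12 symptoms x corrected 9 = 108 at a single timepoint."""
        r = GIResponse("S1", 1, 0, {s: 10 for s in SYMPTOMS})
        rec = correct_and_compose([r])[0]
        assert rec.composite_timepoint == 108

    def test_hand_summed_example(self):
        raw = dict(zip(SYMPTOMS, (3, 1, 1, 1, 1, 1, 2, 5, 6, 1, 1, 1)))
        rec = correct_and_compose([GIResponse("S1", 1, 0, raw)])[0]
        assert rec.composite_timepoint == 12

    def test_correction_is_invertible(self, gi_cohort):
        for rec, resp in zip(correct_and_compose(gi_cohort), gi_cohort):
            assert {s: c + 1 for s, c in rec.corrected.items()} == dict(resp.ratings)


class TestVisitSummaries:
    def test_total_is_sum_of_composites(self, gi_cohort):
        records = correct_and_compose(gi_cohort)
        for summ in visit_summaries(gi_cohort):
            expected = sum(
                r.composite_timepoint for r in records
                if r.subject_id == summ.subject_id and r.visit == summ.visit
            )
            assert summ.total_score == expected

    def test_any_symptom_flag(self):
        quiet = [_response(time_min=t) for t in (0, 30)]
        loud = quiet + [_response(time_min=60, nausea=3)]
        assert not visit_summaries(quiet)[0].any_symptom
        assert visit_summaries(loud)[0].any_symptom


class TestPrevalence:
    def test_any_timepoint_rule_counts_once(self):
        responses = [
            _response("S1", 1, t, urge_to_defecate=4) for t in (0, 30, 60)
        ] + [_response("S2", 1, 0)]
        counts = symptom_prevalence(responses, visit=1)
        assert counts["urge_to_defecate"] == 1
        assert counts["nausea"] == 0

    def test_rating_one_never_counts(self):
        counts = symptom_prevalence([_response("S1", 1, 0)], visit=1)
        assert all(c == 0 for c in counts.values())

    def test_eleven_of_twelve(self):
        responses = [
            _response(f"S{i:02d}", 1, 0,
                      urge_to_defecate=2 if i < 11 else 1)
            for i in range(12)
        ]
        counts = symptom_prevalence(responses, visit=1)
        assert counts["urge_to_defecate"] == 11
        assert 11 / 12 == pytest.approx(0.92, abs=0.005)

    def test_bounds(self, gi_cohort):
        for visit in (1, 2):
            counts = symptom_prevalence(gi_cohort, visit)
            assert all(0 <= c <= 12 for c in counts.values())


class TestComparePrevalence:
    def test_identical_counts_p_one(self):
        counts = {s: 6 for s in SYMPTOMS}
        df = compare_prevalence(counts, counts, n=12)
        assert (df["p_value"] == 1.0).all()
        assert (df["chi2"] == 0.0).all()

    def test_extreme_split_matches_hand_chi2(self):
        """12/12 vs 0/12 with Yates: chi2 = 4 * (5.5^2 / 6) = 20.1667."""
        c1 = {s: 12 if s == "nausea" else 0 for s in SYMPTOMS}
        c2 = {s: 0 for s in SYMPTOMS}
        df = compare_prevalence(c1, c2, n=12).set_index("symptom")
        assert df.loc["nausea", "chi2"] == pytest.approx(20.1667, abs=1e-3)
        assert df.loc["nausea", "p_value"] < 1e-4

    def test_eleven_vs_twelve_not_significant(self):
        c1 = {s: 11 if s == "bloating" else 0 for s in SYMPTOMS}
        c2 = {s: 12 if s == "bloating" else 0 for s in SYMPTOMS}
        df = compare_prevalence(c1, c2, n=12).set_index("symptom")
        assert df.loc["bloating", "p_value"] > 0.05

    def test_low_expected_count_flagged(self):
        c1 = {s: 0 for s in SYMPTOMS}
        c2 = {s: 1 if s == "vomiting" else 0 for s in SYMPTOMS}
        df = compare_prevalence(c1, c2, n=12).set_index("symptom")
        assert bool(df.loc["vomiting", "low_count"])

    def test_counts_above_n_rejected(self):
        with pytest.raises(ValidationError):
            compare_prevalence({s: 13 for s in SYMPTOMS}, {s: 0 for s in SYMPTOMS}, n=12)


class TestGIReliability:
    def test_identical_totals(self):
        responses = [
            _response(f"S{i}", v, t, nausea=3, bloating=2 + i)
            for i in range(4) for v in (1, 2) for t in (0, 30)
        ]
        report = gi_reliability(visit_summaries(responses))
        assert report.te == 0.0
        assert report.icc == pytest.approx(1.0)

    def test_moderate_icc_band(self):
        from bicarbkin.reliability import classify_icc

        assert classify_icc(0.61) == "moderate"

    def test_known_variance_components_recovery(self):
        """Visit totals with known between/within variance recover the population ICC."""
        from bicarbkin.gi import GIVisitSummary

        rng = np.random.default_rng(10)
        sigma_b, sigma_e = 8.0, 4.0
        true_icc = sigma_b**2 / (sigma_b**2 + sigma_e**2)
        iccs = []
        for _ in range(300):
            mu = 40 + sigma_b * rng.standard_normal(50)
            summaries = []
            for v in (1, 2):
                totals = np.maximum(
                    np.rint(mu + sigma_e * rng.standard_normal(50)), 0
                ).astype(int)
                summaries += [
                    GIVisitSummary(f"S{i:02d}", v, int(t), t > 0, {})
                    for i, t in enumerate(totals)
                ]
            iccs.append(gi_reliability(summaries).icc)
        assert float(np.mean(iccs)) == pytest.approx(true_icc, abs=0.05)

    def test_synthetic_cohort_reliability_report(self, gi_cohort):
        report = gi_reliability(visit_summaries(gi_cohort))
        assert report.n_pairs == 12
        assert report.n_pairs + report.n_excluded == 12
        assert -1.0 <= report.icc <= 1.0
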