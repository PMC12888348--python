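#!/usr/bin/env python
"""Test-retest reliability of the six kinetic metrics between visits.

Computes ICC(2,1) with McGraw-Wong 95% CI, typical error and CV with
chi-square-scaled 95% CIs, paired-comparison p-values, difference ranges
and interpretation bands; subjects who never reach a threshold in one
visit are removed by listwise deletion and counted. Writes
results/reliability.csv.
"""

from pathlib import Path

from bicarbkin.data_io import RunConfig, read_bicarb_table
from bicarbkin.kinetics import extract_all
from bicarbkin.reliability import reliability_table, reports_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig()
    series = read_bicarb_table(ROOT / "data" / "cohort.csv")
    metrics = [extract_all(s, config) for s in series]
    reports = reliability_table(metrics, config)
    reports_frame(reports).to_csv(ROOT / "reliability.csv", index=False)

    print(f"{'metric':<12}{'n':>4}{'excl':>6}{'ICC':>8}{'TE':>9}{'CV%':>8}  band")
    for r in reports:
        print(f"{r.metric:<12}{r.n_pairs:>4}{r.n_excluded:>6}"
              f"{r.icc:>8.2f}{r.te:>9.2f}{r.cv_pct:>8.1f}  {r.icc_band}")


if __name__ == "__main__":
    main()
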