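#!/usr/bin/env python
"""Render the study figures from the generated cohort: mean +/- SD time
course, paired-metric lines per subject, exceedance probabilities with the
80% cutoff line, and GI prevalence bars. Writes PNGs under results/figures/.
"""

from pathlib import Path

from bicarbkin.data_io import RunConfig, read_bicarb_table, read_gi_table
from bicarbkin.pipeline import make_figures, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    series = read_bicarb_table(ROOT / "data" / "cohort.csv")
    responses = read_gi_table(ROOT / "data" / "gi.csv")
    result = run_pipeline(series, responses, RunConfig(rng_seed=SEED))
    paths = make_figures(series, result, ROOT / "figures", responses)
    for p in paths:
        print("wrote", p.relative_to(ROOT.parent))


if __name__ == "__main__":
    main()
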