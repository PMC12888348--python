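"""Per-subject-visit kinetic summary metrics from the 1-minute interpolated profile.

Six metrics: baseline (observed value at 0 min), absolute peak concentration
Cmax, time to peak TTP (earliest minute on a plateau of equal maxima),
earliest minutes at which the profile meets or exceeds baseline +5 and
+6 mmol/L (missing if never reached by the end of the grid), and total AUC
by trapezoidal integration over the grid. Peaks may legitimately occur at
the grid boundaries because endpoints are included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_io import BicarbSeries, RunConfig, ValidationError
from .interp import InterpolatedProfile, pchip_interpolate

#: Sentinel for a threshold never reached within the observation window.
MISSING = None


@dataclass(frozen=True)
class KineticMetrics:
    """The six summary metrics for one subject-visit.

    time_to_delta maps each threshold increase (mmol/L) to the earliest
    minute it is met, or None when the threshold is never reached
    (missing, handled downstream by listwise deletion).
    """

    subject_id: str
    visit: int
    baseline: float
    cmax: float
    ttp_min: float
    time_to_delta: Mapping[float, float | None] = field(default_factory=dict)
    auc: float = 0.0


def extract_baseline(profile: InterpolatedProfile) -> float:
    """Baseline is the observed value at 0 minutes (equal to the t=0 grid value)."""
    if profile.grid[0] != 0:
        raise ValidationError("baseline requires a grid starting at 0 min")
    return float(profile.values[0])


def extract_peak(profile: InterpolatedProfile, plateau_tol: float = 0.0) -> tuple[float, int]:
    """Global maximum of the profile and the earliest minute attaining it.

    plateau_tol widens the plateau test (value >= cmax - tol); the default 0
    is exact float equality, appropriate for a deterministic interpolant.
    """
    cmax = float(np.max(profile.values))
    on_plateau = profile.values >= cmax - plateau_tol
    ttp = int(profile.grid[int(np.argmax(on_plateau))])
    return cmax, ttp


def time_to_threshold(
    profile: InterpolatedProfile, baseline: float, delta: float
) -> float | None:
    """Earliest grid minute with value >= baseline + delta, or None if never reached."""
    if delta <= 0:
        raise ValidationError("threshold delta must be positive")
    hit = profile.values >= baseline + delta
    if not hit.any():
        return MISSING
    return float(profile.grid[int(np.argmax(hit))])


def compute_auc(profile: InterpolatedProfile) -> float:
    """Total area under the curve by the trapezoid rule on the 1-minute grid (mmol*min/L)."""
    return float(np.trapezoid(profile.values, profile.grid))


def extract_all(series: BicarbSeries, config: RunConfig | None = None) -> KineticMetrics:
    """Interpolate one series and derive all six metrics."""
    config = config or RunConfig()
    profile = pchip_interpolate(series, config.grid_start_min, config.grid_end_min)
    return extract_from_profile(profile, config)


def extract_from_profile(
    profile: InterpolatedProfile, config: RunConfig | None = None
) -> KineticMetrics:
    """Derive the six metrics from an already interpolated profile."""
    config = config or RunConfig()
    baseline = extract_baseline(profile)
    cmax, ttp = extract_peak(profile)
    ttd = {
        float(d): time_to_threshold(profile, baseline, d) for d in config.thresholds
    }
    return KineticMetrics(
        subject_id=profile.subject_id,
        visit=profile.visit,
        baseline=baseline,
        cmax=cmax,
        ttp_min=ttp,
        time_to_delta=ttd,
        auc=compute_auc(profile),
    )


def metrics_frame(metrics: list[KineticMetrics]):
    """Tabulate metrics, one row per subject-visit; missing threshold times as NaN."""
    import pandas as pd

    thresholds = sorted({d for m in metrics for d in m.time_to_delta})
    rows = []
    for m in metrics:
        row = {
            "subject": m.subject_id,
            "visit": m.visit,
            "baseline": m.baseline,
            "cmax": m.cmax,
            "ttp_min": m.ttp_min,
            "auc": m.auc,
        }
        for d in thresholds:
            t = m.time_to_delta.get(d, MISSING)
            row[f"t_plus{d:g}_min"] = math.nan if t is MISSING else t
        rows.append(row)
    return pd.DataFrame(rows)
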