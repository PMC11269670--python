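"""End-to-end convenience pipeline: plates -> fits -> normalization ->
burden table -> capacity analysis.

Thin glue over the stage modules, used by the CLI, the test-suite
round-trips, and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import capacity as _capacity
from . import normstats, plate_assay
from .normstats import BurdenResult
from .synthdata import CohortData

# 0.014 per hour, the field-standard growth-rate smoothing bandwidth,
# expressed on the per-minute rate scale used by the window fits.
GROWTH_BANDWIDTH_PER_MIN = normstats.GROWTH_BANDWIDTH / 60.0


@dataclass
class CohortAnalysis:
    fits: pd.DataFrame
    normalized: pd.DataFrame
    burden: pd.DataFrame
    burden_results: dict[str, BurdenResult]
    line: _capacity.CapacityLine | None = None
    capacity: pd.DataFrame | None = None


def fit_plates(plates, window_pts: int = 9, od_min: float = 0.03) -> pd.DataFrame:
    """Correct and fit every plate; concatenate the fits tables."""
    return pd.concat(
        [plate_assay.fit_plate(p, window_pts=window_pts, od_min=od_min) for p in plates],
        ignore_index=True,
    )


def analyze_cohort(
    cohort: CohortData,
    growth_bandwidth: float = GROWTH_BANDWIDTH_PER_MIN,
    production_bandwidth: float = normstats.PRODUCTION_BANDWIDTH,
    fdr: float = 0.05,
    run_capacity: bool = True,
    annotations=None,
    n_mc: int = 20_000,
    n_boot: int = 500,
    seed: int = 0,
) -> CohortAnalysis:
    """Full analysis of a synthetic cohort.

    Fits every plate, normalizes plate by plate, builds the burden table,
    and (optionally) fits the anchored Deming capacity line on the control
    strains' per-plate means and classifies burden sources.  Parts default
    to fluorophore-free annotations unless ``annotations`` says otherwise.
    """
    channel = cohort.config.channel
    fits = fit_plates(cohort.plates)
    normalized = normstats.normalize_fits(
        fits, growth_bandwidth=growth_bandwidth, production_bandwidth=production_bandwidth
    )
    burden_df, results = normstats.burden_table(normalized, fdr=fdr)
    out = CohortAnalysis(
        fits=fits, normalized=normalized, burden=burden_df, burden_results=results
    )
    if run_capacity:
        ctrl = normalized[normalized["role"] == "control"]
        per_plate = (
            ctrl.groupby(["plate", "strain"])[["normalized_r", f"normalized_p_{channel}"]]
            .mean()
            .dropna()
        )
        line = _capacity.fit_anchored_deming(
            per_plate[f"normalized_p_{channel}"], per_plate["normalized_r"]
        )
        if annotations is None:
            annotations = {part: [] for part in results}
        out.line = line
        out.capacity = _capacity.classify_burden_sources(
            normalized, results, line, annotations,
            channel=channel, fdr=fdr, n_mc=n_mc, n_boot=n_boot, seed=seed,
        )
    return out
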