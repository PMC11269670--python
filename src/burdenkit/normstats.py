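"""Plate normalization by KDE peak detection and burden statistics.

Most strains on any given assay plate carry negligible-burden constructs,
so the mode of the plate's rate distribution marks the "no-burden" rate.
Plates are normalized by dividing every rate by that per-plate reference,
found as the right-most peak, among peaks at least half as high as the
tallest, of a Gaussian kernel density estimate of the non-control rates
(default bandwidths: 0.014 for growth rates per minute, 300 for GFP
production rates in instrument units).

Burden is then ``100 * (1 - normalized growth rate)`` percent.  Per part,
one-sample one-tailed t-tests ask whether mean burden exceeds each of a
set of thresholds (0, 10, 20, 30, 45 %), with Benjamini--Hochberg control
of the false discovery rate across parts for the burden-vs-zero test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PlateNormalization",
    "BurdenResult",
    "kde_density",
    "no_burden_reference",
    "normalize_plate",
    "normalize_fits",
    "burden_summary",
    "burden_table",
    "bh_adjust",
    "sem_burden_trend",
    "DEFAULT_THRESHOLDS",
    "GROWTH_BANDWIDTH",
    "PRODUCTION_BANDWIDTH",
]

DEFAULT_THRESHOLDS = (0.0, 10.0, 20.0, 30.0, 45.0)
GROWTH_BANDWIDTH = 0.014
PRODUCTION_BANDWIDTH = 300.0
KDE_GRID_POINTS = 2048


@dataclass(frozen=True)
class PlateNormalization:
    """Per-plate no-burden reference and normalized values."""

    plate_id: str
    metric: str
    bandwidth: float
    no_burden_value: float
    normalized: pd.Series  # indexed like the input measurements

    def __post_init__(self) -> None:
        if self.no_burden_value <= 0:
            raise ValueError("no-burden reference must be positive")


@dataclass(frozen=True)
class BurdenResult:
    """Burden summary for one part across plates/replicates."""

    part: str
    n: int
    mean_burden: float  # percent reduction in growth rate
    ci95: float  # half-width of the 95% CI, percent
    sem: float  # standard error of the mean burden, percent
    p_raw: dict[float, float]  # threshold (percent) -> one-tailed p
    p_bh: float = np.nan  # BH-adjusted p for the burden-vs-0 test
    significant: bool = False
    testable: bool = True


# ---------------------------------------------------------------------------
# KDE and the no-burden rule


def kde_density(
    values, bandwidth: float, grid
) -> np.ndarray:
    """Gaussian KDE evaluated on ``grid``: mean of N(v, bandwidth^2) kernels.

    The bandwidth is the kernel standard deviation in the units of the data.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size == 0:
        raise ValueError("kde_density needs at least one value")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z**2).sum(axis=1) / (values.size * bandwidth * np.sqrt(2 * np.pi))


def default_grid(values, bandwidth: float, n: int = KDE_GRID_POINTS) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return np.linspace(values.min() - 4 * bandwidth, values.max() + 4 * bandwidth, n)


def no_burden_reference(values, bandwidth: float, grid=None) -> float:
    """The per-plate no-burden rate.

    Finds all strict local maxima of the KDE on a dense grid; among peaks
    whose height is at least 50% of the tallest peak, returns the location
    of the right-most (largest-rate) one.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("no_burden_reference needs at least 3 values")
    if grid is None:
        grid = default_grid(values, bandwidth)
    dens = kde_density(values, bandwidth, grid)
    interior = np.arange(1, len(grid) - 1)
    # local maximum, allowing an exact tie on one side (plateau of 2 points
    # occurs when the density is symmetric about a grid midpoint)
    is_peak = (
        (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    ) | ((dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1]))
    peaks = interior[is_peak]
    if peaks.size == 0:  # flat density (cannot happen with 4-bandwidth padding)
        peaks = np.array([int(np.argmax(dens))])
    tall = peaks[dens[peaks] >= 0.5 * dens[peaks].max()]
    win = int(tall.max())
    # refine the winning peak within its grid bracket
    from scipy.optimize import minimize_scalar

    lo = grid[max(win - 1, 0)]
    hi = grid[min(win + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: -kde_density(values, bandwidth, np.array([x]))[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": bandwidth * 1e-9},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Normalization


def normalize_plate(
    fits: pd.DataFrame, metric: str, bandwidth: float, plate_id: str | None = None
) -> PlateNormalization:
    """Normalize one plate's fits by its no-burden reference rate.

    The reference is estimated from non-control (role == "test") wells
    with a successful fit; every well, controls included, is then divided
    by it.
    """
    ok = fits["status"] == "ok" if "status" in fits.columns else pd.Series(True, index=fits.index)
    test_vals = fits.loc[(fits["role"] == "test") & ok, metric].dropna().to_numpy()
    if plate_id is None:
        plate_id = str(fits["plate"].iloc[0]) if "plate" in fits.columns else "plate1"
    if test_vals.size < 3:
        raise ValueError(f"plate {plate_id}: fewer than 3 non-control measurements of {metric}")
    ref = no_burden_reference(test_vals, bandwidth)
    return PlateNormalization(
        plate_id=plate_id,
        metric=metric,
        bandwidth=bandwidth,
        no_burden_value=ref,
        normalized=fits[metric] / ref,
    )


def normalize_fits(
    fits: pd.DataFrame,
    growth_bandwidth: float = GROWTH_BANDWIDTH,
    production_bandwidth: float = PRODUCTION_BANDWIDTH,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Normalize a multi-plate fits table plate by plate.

    Adds ``normalized_r`` plus ``normalized_p_<channel>`` columns and the
    per-plate reference values used.
    """
    if channels is None:
        channels = [c[len("p_max_") :] for c in fits.columns if c.startswith("p_max_")]
    out = fits.copy()
    out["normalized_r"] = np.nan
    out["ref_r"] = np.nan
    for ch in channels:
        out[f"normalized_p_{ch}"] = np.nan
        out[f"ref_p_{ch}"] = np.nan
    for plate_id, grp in fits.groupby("plate"):
        norm = normalize_plate(grp, "r_max", growth_bandwidth, str(plate_id))
        out.loc[grp.index, "normalized_r"] = norm.normalized
        out.loc[grp.index, "ref_r"] = norm.no_burden_value
        for ch in channels:
            pn = normalize_plate(grp, f"p_max_{ch}", production_bandwidth, str(plate_id))
            out.loc[grp.index, f"normalized_p_{ch}"] = pn.normalized
            out.loc[grp.index, f"ref_p_{ch}"] = pn.no_burden_value
    return out


# ---------------------------------------------------------------------------
# Burden statistics


def _one_tailed_greater(values: np.ndarray, popmean: float) -> float:
    """One-sample t-test p-value for mean > popmean, with the zero-variance
    convention: p = 0 if the mean strictly exceeds the threshold, else 1."""
    if np.std(values, ddof=1) == 0:
        return 0.0 if values.mean() > popmean else 1.0
    res = stats.ttest_1samp(values, popmean, alternative="greater")
    return float(res.pvalue)


def burden_summary(
    part: str,
    normalized_rates,
    thresholds=DEFAULT_THRESHOLDS,
) -> BurdenResult:
    """Burden estimate and threshold tests for one part.

    ``normalized_rates`` are that part's normalized growth-rate
    measurements pooled across plates.  Burden per measurement is
    ``100 * (1 - rate)`` percent; a one-tailed t-test is run against each
    threshold (also percent).  Parts with fewer than 2 measurements are
    flagged untestable.
    """
    rates = np.asarray(normalized_rates, dtype=float)
    rates = rates[~np.isnan(rates)]
    burdens = 100.0 * (1.0 - rates)
    n = burdens.size
    if n == 0:
        raise ValueError(f"part {part}: no measurements")
    mean = float(burdens.mean())
    if n < 2:
        return BurdenResult(
            part=part, n=n, mean_burden=mean, ci95=np.nan, sem=np.nan,
            p_raw={float(th): np.nan for th in thresholds}, testable=False,
        )
    sem = float(stats.sem(burdens))
    ci95 = float(stats.t.ppf(0.975, n - 1) * sem)
    p_raw = {float(th): _one_tailed_greater(burdens, float(th)) for th in thresholds}
    return BurdenResult(part=part, n=n, mean_burden=mean, ci95=ci95, sem=sem, p_raw=p_raw)


def bh_adjust(pvals, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini--Hochberg step-up adjusted p-values and rejections at ``fdr``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return p_adj, reject


def burden_table(
    normalized: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    fdr: float = 0.05,
    part_column: str = "strain",
) -> tuple[pd.DataFrame, dict[str, BurdenResult]]:
    """Per-part burden table from a normalized fits table (test parts only).

    BH adjustment is applied across parts to the burden-vs-0 p-values; the
    returned DataFrame has one row per part with burden, CI, raw p per
    threshold and the adjusted p / significance call.
    """
    tests = normalized[normalized["role"] == "test"]
    results: dict[str, BurdenResult] = {}
    for part, grp in tests.groupby(part_column):
        ok = grp["status"] == "ok" if "status" in grp.columns else slice(None)
        vals = grp.loc[ok, "normalized_r"].dropna()
        if len(vals) == 0:
            continue
        results[str(part)] = burden_summary(str(part), vals.to_numpy(), thresholds)
    testable = [p for p, r in results.items() if r.testable]
    if testable:
        p_adj, reject = bh_adjust([results[p].p_raw[0.0] for p in testable], fdr)
        for part, pa, rej in zip(testable, p_adj, reject):
            r = results[part]
            results[part] = BurdenResult(
                part=r.part, n=r.n, mean_burden=r.mean_burden, ci95=r.ci95,
                sem=r.sem, p_raw=r.p_raw, p_bh=float(pa), significant=bool(rej),
            )
    rows = []
    for part, r in results.items():
        row = {
            "part": part, "n": r.n, "burden_pct": r.mean_burden, "ci95": r.ci95,
            "sem": r.sem, "p_bh_0": r.p_bh, "significant": r.significant,
            "testable": r.testable,
        }
        for th, p in r.p_raw.items():
            row[f"p_raw_{th:g}"] = p
        rows.append(row)
    return pd.DataFrame(rows), results


def sem_burden_trend(results) -> tuple[float, float]:
    """Test for a trend of measurement SEM with burden across parts.

    Ordinary least-squares regression of each part's SEM of the growth-rate
    burden on its mean burden; returns (slope, two-tailed p for a non-zero
    slope).  A positive slope indicates that more burdensome parts are
    measured less reproducibly, as expected if escape mutants are taking
    over some replicate cultures.
    """
    if isinstance(results, dict):
        results = list(results.values())
    pts = [(r.mean_burden, r.sem) for r in results if r.testable and np.isfinite(r.sem)]
    if len(pts) < 3:
        raise ValueError("sem_burden_trend needs at least 3 parts")
    x, y = np.array(pts).T
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.pvalue)
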