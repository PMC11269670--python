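"""Gene-expression capacity analysis: anchored Deming regression and the
decomposition of burden into expression vs other sources.

The host strain carries a chromosomal constitutive GFP cassette whose
production rate reports how much gene-expression capacity (chiefly
ribosomes) remains available.  If all of a construct's burden comes from
consuming that shared capacity, its normalized growth rate ``y`` and
normalized GFP production rate ``x`` fall on a line through the no-burden
anchor (1, 1) whose slope is estimated from control strains by Deming
regression (errors in both variables, variance ratio ``lambda``).

A part lying below that line — growth reduced more than its GFP production
predicts — carries "other burden".  For each eligible part, location-scale
t distributions are fitted by maximum likelihood to its growth-rate and
GFP-production measurements; Monte-Carlo draws from the independent 2-D
distribution give the probability mass on the null-consistent side of the
line, i.e. a one-tailed p-value for rejecting the hypothesis that all
burden is expression burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normstats import BurdenResult, bh_adjust

__all__ = [
    "CapacityLine",
    "OtherBurdenResult",
    "fit_anchored_deming",
    "interference_filter",
    "other_burden_test",
    "classify_burden_sources",
    "INTERFERING_FLUOROPHORES",
]

# Proteins that interfere with the GFP fluorescence readout: GFP itself,
# YFP (overlapping emission), and the amilCP chromoprotein (absorbs at the
# monitored emission wavelength).
INTERFERING_FLUOROPHORES = frozenset({"GFP", "YFP", "AMILCP"})

DEFAULT_ANCHOR = (1.0, 1.0)


@dataclass(frozen=True)
class CapacityLine:
    """Expression-burden trade-off line, constrained through the anchor.

    ``slope`` relates normalized growth rate (y) to normalized GFP
    production (x): ``y = ay + slope * (x - ax)``.
    """

    slope: float
    anchor: tuple[float, float] = DEFAULT_ANCHOR
    lam: float = 1.0
    n_points: int = 0

    def predict_growth(self, gfp) -> np.ndarray:
        ax, ay = self.anchor
        return ay + self.slope * (np.asarray(gfp, dtype=float) - ax)

    def signed_offset(self, gfp, growth) -> np.ndarray:
        """Positive above the line (growth higher than predicted); the
        other-burden alternative lies at negative offsets."""
        return np.asarray(growth, dtype=float) - self.predict_growth(gfp)


@dataclass(frozen=True)
class OtherBurdenResult:
    """Decomposition of one part's burden into expression vs other sources."""

    part: str
    burden: float  # total burden b, percent
    burden_expression: float  # b_GE predicted from the capacity line, percent
    burden_other: float  # b_O = b - b_GE, percent
    frac_other: float  # b_O / b
    frac_interval: tuple[float, float]  # bootstrap 95% interval on b_O / b
    p: float  # one-tailed p, null: all burden is expression burden
    p_bh: float = np.nan
    n: int = 0
    excluded: bool = False
    excluded_reason: str | None = None


# ---------------------------------------------------------------------------
# Anchored Deming regression


def fit_anchored_deming(
    x, y, anchor: tuple[float, float] = DEFAULT_ANCHOR, lam: float = 1.0
) -> CapacityLine:
    """Deming regression of y on x for a line constrained through ``anchor``.

    Minimizes the errors-in-variables objective
    ``sum (v_i - m u_i)^2 / (lam + m^2)`` over the slope ``m``, where
    ``(u, v)`` are coordinates relative to the anchor and ``lam`` is the
    ratio of the y to x error variances.  Closed form via the second
    moments about the anchor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 (x, y) points")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    u = x - anchor[0]
    v = y - anchor[1]
    suu = float(u @ u)
    svv = float(v @ v)
    suv = float(u @ v)
    if suu == 0 and svv == 0:
        raise ValueError("all points coincide with the anchor")
    if suv == 0:
        # Degenerate: objective is monotone between the axes; pick the axis
        # with less mass under the lam weighting.
        slope = 0.0 if svv <= lam * suu else np.inf
    else:
        slope = (svv - lam * suu + np.hypot(svv - lam * suu, 2 * np.sqrt(lam) * suv)) / (
            2 * suv
        )
    return CapacityLine(slope=float(slope), anchor=anchor, lam=lam, n_points=x.size)


# ---------------------------------------------------------------------------
# Interference filtering


def interference_filter(annotations) -> pd.DataFrame:
    """Classify parts by whether they interfere with the GFP readout.

    ``annotations`` maps part id -> iterable of fluorophore tags (an empty
    collection means the part is annotated as containing no fluorescent
    protein).  Parts tagged GFP, YFP or amilCP are excluded; parts with a
    missing (None/NaN) annotation are excluded with an "unannotated"
    warning; everything else (including RFP/BFP-tagged parts) is included.
    """
    rows = []
    for part, tags in dict(annotations).items():
        if tags is None or (np.isscalar(tags) and pd.isna(tags)):
            warnings.warn(f"part {part}: no fluorophore annotation; excluded", stacklevel=2)
            rows.append((part, False, "unannotated"))
            continue
        if isinstance(tags, str):
            tags = [t for t in tags.replace(";", ",").split(",") if t.strip()]
        upper = {str(t).strip().upper() for t in tags}
        hits = upper & INTERFERING_FLUOROPHORES
        if hits:
            rows.append((part, False, "+".join(sorted(hits))))
        else:
            rows.append((part, True, None))
    return pd.DataFrame(rows, columns=["part", "included", "excluded_reason"]).set_index(
        "part"
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood t fits and the other-burden test

# Below this sample size the t degrees of freedom are fixed at n - 1 rather
# than fitted (the likelihood surface in df is too flat to be useful).
SMALL_SAMPLE_N = 10
MIN_DF = 3.0


def _fit_t(values: np.ndarray) -> tuple[float, float, float]:
    """ML location-scale t fit; returns (df, loc, scale)."""
    n = values.size
    if n < 3:
        raise ValueError("ML t fit needs at least 3 measurements")
    if np.std(values) == 0:
        return float(max(n - 1, MIN_DF)), float(values.mean()), 1e-12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n < SMALL_SAMPLE_N:
            df = float(max(n - 1, MIN_DF))
            _, loc, scale = stats.t.fit(values, f0=df)
        else:
            df, loc, scale = stats.t.fit(values)
            if df < MIN_DF:
                df = MIN_DF
                _, loc, scale = stats.t.fit(values, f0=df)
    return float(df), float(loc), float(scale)


def other_burden_test(
    part: str,
    growth,
    gfp,
    line: CapacityLine,
    n_mc: int = 100_000,
    seed: int = 0,
    n_boot: int = 1000,
    halve_above: bool = False,
    annotation=None,
) -> OtherBurdenResult:
    """Test whether a part's burden exceeds its expression burden.

    ``growth`` and ``gfp`` are the part's normalized growth-rate and GFP
    production-rate measurements.  Independent ML t distributions for the
    two axes define a 2-D distribution for the part's true position;
    ``n_mc`` Monte-Carlo draws estimate the probability mass on the
    null-consistent side of the capacity line (on or above it), which is
    the default one-tailed p-value — small when the part sits clearly
    below the line, i.e. its growth is reduced more than its GFP
    production predicts.  ``halve_above=True`` instead reports half the
    mass on the alternative side (a literal-convention compatibility
    mode).  The 95% interval on the other-burden fraction ``b_O / b``
    comes from a parametric bootstrap of the fitted distributions and is
    deliberately not truncated to [0, 1].
    """
    if annotation is not None:
        filt = interference_filter({part: annotation})
        if not filt.loc[part, "included"]:
            raise ValueError(
                f"part {part} is excluded by the fluorescence interference filter "
                f"({filt.loc[part, 'excluded_reason']})"
            )
    growth = np.asarray(growth, dtype=float)
    gfp = np.asarray(gfp, dtype=float)
    growth = growth[~np.isnan(growth)]
    gfp = gfp[~np.isnan(gfp)]
    rng = np.random.default_rng(seed)

    dfg, locg, scaleg = _fit_t(growth)
    dfx, locx, scalex = _fit_t(gfp)
    # ML scale carries the 1/n small-sample bias; correct as with sigma-hat.
    scaleg *= np.sqrt(growth.size / max(growth.size - 1, 1))
    scalex *= np.sqrt(gfp.size / max(gfp.size - 1, 1))

    # The tested object is the part's true position, so the 2-D t is scaled
    # to the uncertainty of the mean, not the measurement-level scatter.
    se_y = scaleg / np.sqrt(growth.size)
    se_x = scalex / np.sqrt(gfp.size)
    draws_y = stats.t.rvs(dfg, loc=locg, scale=se_y, size=n_mc, random_state=rng)
    draws_x = stats.t.rvs(dfx, loc=locx, scale=se_x, size=n_mc, random_state=rng)
    offsets = line.signed_offset(draws_x, draws_y)
    if halve_above:
        p = 0.5 * float(np.mean(offsets < 0))
    else:
        p = float(np.mean(offsets >= 0))

    b = 100.0 * (1.0 - growth.mean())
    b_ge = 100.0 * (1.0 - float(line.predict_growth(gfp.mean())))
    b_o = b - b_ge
    frac = b_o / b if b != 0 else np.nan

    # Parametric bootstrap on the fraction: resample measurement sets of the
    # observed sizes from the fitted distributions.
    fracs = np.empty(n_boot)
    for i in range(n_boot):
        gy = stats.t.rvs(dfg, loc=locg, scale=scaleg, size=growth.size, random_state=rng)
        gx = stats.t.rvs(dfx, loc=locx, scale=scalex, size=gfp.size, random_state=rng)
        bb = 100.0 * (1.0 - gy.mean())
        bge = 100.0 * (1.0 - float(line.predict_growth(gx.mean())))
        fracs[i] = (bb - bge) / bb if bb != 0 else np.nan
    lo, hi = np.nanpercentile(fracs, [2.5, 97.5])

    return OtherBurdenResult(
        part=part,
        burden=b,
        burden_expression=b_ge,
        burden_other=b_o,
        frac_other=frac,
        frac_interval=(float(lo), float(hi)),
        p=p,
        n=int(growth.size),
    )


def classify_burden_sources(
    normalized: pd.DataFrame,
    burden_results: dict[str, BurdenResult],
    line: CapacityLine,
    annotations,
    channel: str = "GFP",
    fdr: float = 0.05,
    min_burden: float = 10.0,
    n_mc: int = 100_000,
    seed: int = 0,
    n_boot: int = 1000,
    halve_above: bool = False,
    part_column: str = "strain",
) -> pd.DataFrame:
    """Run the other-burden test across a cohort and BH-adjust.

    Eligible parts have burden significantly greater than zero (BH-adjusted),
    mean burden above ``min_burden`` percent, and no fluorescence
    interference.  Returns one row per part with the burden decomposition,
    interval, raw and adjusted p-values, or the exclusion reason.
    """
    filt = interference_filter(annotations)
    tests = normalized[normalized["role"] == "test"]
    seeds = np.random.SeedSequence(seed)
    rows = []
    eligible: list[OtherBurdenResult] = []
    for part, res in burden_results.items():
        reason = None
        if part in filt.index and not filt.loc[part, "included"]:
            reason = str(filt.loc[part, "excluded_reason"])
        elif part not in filt.index:
            reason = "unannotated"
        elif not res.significant:
            reason = "burden not significant"
        elif res.mean_burden <= min_burden:
            reason = f"mean burden <= {min_burden:g}%"
        if reason is not None:
            rows.append(
                OtherBurdenResult(
                    part=part, burden=res.mean_burden, burden_expression=np.nan,
                    burden_other=np.nan, frac_other=np.nan,
                    frac_interval=(np.nan, np.nan), p=np.nan, n=res.n,
                    excluded=True, excluded_reason=reason,
                )
            )
            continue
        grp = tests[tests[part_column] == part]
        ok = grp["status"] == "ok" if "status" in grp.columns else slice(None)
        growth = grp.loc[ok, "normalized_r"].dropna().to_numpy()
        gfp = grp.loc[ok, f"normalized_p_{channel}"].dropna().to_numpy()
        sub_seed = int(seeds.spawn(1)[0].generate_state(1)[0] % (2**31))
        result = other_burden_test(
            part, growth, gfp, line, n_mc=n_mc, seed=sub_seed,
            n_boot=n_boot, halve_above=halve_above,
        )
        eligible.append(result)
    if eligible:
        p_adj, reject = bh_adjust([r.p for r in eligible], fdr)
        eligible = [
            OtherBurdenResult(
                part=r.part, burden=r.burden, burden_expression=r.burden_expression,
                burden_other=r.burden_other, frac_other=r.frac_other,
                frac_interval=r.frac_interval, p=r.p, p_bh=float(pa), n=r.n,
            )
            for r, pa in zip(eligible, p_adj)
        ]
    rows.extend(eligible)
    table = pd.DataFrame(
        {
            "part": [r.part for r in rows],
            "n": [r.n for r in rows],
            "b": [r.burden for r in rows],
            "b_GE": [r.burden_expression for r in rows],
            "b_O": [r.burden_other for r in rows],
            "frac_other": [r.frac_other for r in rows],
            "frac_lo": [r.frac_interval[0] for r in rows],
            "frac_hi": [r.frac_interval[1] for r in rows],
            "p": [r.p for r in rows],
            "p_bh": [r.p_bh for r in rows],
            "excluded_reason": [r.excluded_reason for r in rows],
        }
    )
    if table.empty:
        table.attrs["note"] = "no eligible parts"
    return table
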