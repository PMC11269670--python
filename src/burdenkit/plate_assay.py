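"""Microplate growth-curve ingestion, correction and window fitting.

A burden assay plate is a 96-well plate read every ~10 minutes for optical
density (OD600, or OD660 for RFP-bearing strains) and one or more
fluorescence channels.  This module:

- reads long-format run CSVs plus a well layout table into :class:`Plate`;
- subtracts the per-timepoint mean of the media blanks;
- aligns replicate baselines so each strain's first-hour mean matches the
  across-replicate grand mean;
- fits the maximum specific growth rate ``r`` by scanning all windows of
  nine consecutive points after OD exceeds 0.03 with the exponential model
  ``C(t) = C0 * exp(r t)`` (nonlinear least squares per window);
- fits the maximum fluorescent-protein production rate ``p`` per channel
  with ``F(t) = F0 + C0 (p / r) (exp(r t) - 1)``, obtained by integrating
  ``dF/dt = p C(t)`` with ``C0`` and ``r`` frozen per window.

OD is treated as directly proportional to cell number; rates are per
minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PlateFormatError",
    "PlateLayout",
    "WellInfo",
    "WellSeries",
    "Plate",
    "WellFit",
    "WindowFit",
    "read_plate",
    "write_plate",
    "subtract_blanks",
    "align_baselines",
    "fit_max_growth_rate",
    "fit_max_production_rate",
    "fit_plate",
]

OD_CHANNELS = ("OD600", "OD660")
ROLES = ("test", "control", "blank")


class PlateFormatError(ValueError):
    """Raised for malformed run or layout files."""


@dataclass(frozen=True)
class WellInfo:
    strain: str | None
    role: str
    replicate: int = 1


@dataclass
class PlateLayout:
    plate_id: str
    wells: dict[str, WellInfo]
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for well, info in self.wells.items():
            if info.role not in ROLES:
                raise PlateFormatError(f"well {well}: unknown role {info.role!r}")
            if info.role == "blank" and info.strain not in (None, ""):
                raise PlateFormatError(f"blank well {well} must have no strain")
            if info.role != "blank" and not info.strain:
                raise PlateFormatError(f"well {well} with role {info.role} needs a strain")

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, i in self.wells.items() if i.role == role]

    @property
    def od_channel(self) -> str:
        for ch in OD_CHANNELS:
            if ch in self.channels:
                return ch
        raise PlateFormatError(f"no OD channel among {self.channels}")

    @property
    def fluor_channels(self) -> list[str]:
        return [c for c in self.channels if c not in OD_CHANNELS]


@dataclass
class WellSeries:
    """One well's time series: uniformly sampled OD plus fluorescence."""

    well: str
    times: np.ndarray
    od: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if np.any(np.diff(self.times) <= 0):
            raise PlateFormatError(f"well {self.well}: times not strictly increasing")
        if self.od.shape != self.times.shape:
            raise PlateFormatError(f"well {self.well}: OD length mismatch")
        for ch, v in self.channels.items():
            if v.shape != self.times.shape:
                raise PlateFormatError(f"well {self.well}: channel {ch} length mismatch")

    def copy(self) -> "WellSeries":
        return WellSeries(
            self.well,
            self.times.copy(),
            self.od.copy(),
            {k: v.copy() for k, v in self.channels.items()},
        )


@dataclass
class Plate:
    layout: PlateLayout
    wells: dict[str, WellSeries]

    @property
    def plate_id(self) -> str:
        return self.layout.plate_id

    def copy(self) -> "Plate":
        return Plate(self.layout, {w: s.copy() for w, s in self.wells.items()})


@dataclass
class WindowFit:
    """Exponential fit to one window of consecutive points."""

    start: int
    C0: float
    r: float
    r2: float
    t0: float  # time of the window's first point (fit origin)


@dataclass
class WellFit:
    """Winning-window growth and production rates for one well."""

    well: str
    status: str  # ok | no_growth | fit_failed
    r_max: float = np.nan
    C0: float = np.nan
    window_index: int = -1
    r2: float = np.nan
    p_max: dict[str, float] = field(default_factory=dict)
    F0: dict[str, float] = field(default_factory=dict)
    p_window_index: dict[str, int] = field(default_factory=dict)
    window_fits: list[WindowFit] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)
    window_pts: int = 9


# ---------------------------------------------------------------------------
# Reading / writing


def read_plate(run_file, layout_file, plate_id: str | None = None) -> Plate:
    """Read a long-format run CSV and its layout CSV into a :class:`Plate`.

    Run columns: ``well,time_min,channel,value``.  Layout columns:
    ``well,strain,role,replicate``.
    """
    run = pd.read_csv(run_file)
    lay = pd.read_csv(layout_file)
    for col in ("well", "time_min", "channel", "value"):
        if col not in run.columns:
            raise PlateFormatError(f"run file missing column {col!r}")
    for col in ("well", "strain", "role"):
        if col not in lay.columns:
            raise PlateFormatError(f"layout file missing column {col!r}")
    if run.duplicated(["well", "time_min", "channel"]).any():
        dup = run[run.duplicated(["well", "time_min", "channel"])].iloc[0]
        raise PlateFormatError(
            f"duplicate measurement for well {dup.well} t={dup.time_min} channel {dup.channel}"
        )

    wells_info: dict[str, WellInfo] = {}
    for row in lay.itertuples(index=False):
        strain = None if pd.isna(row.strain) or row.strain == "" else str(row.strain)
        rep = int(getattr(row, "replicate", 1)) if hasattr(row, "replicate") else 1
        wells_info[str(row.well)] = WellInfo(strain=strain, role=str(row.role), replicate=rep)

    data_wells = set(run["well"].astype(str))
    missing = data_wells - set(wells_info)
    if missing:
        raise PlateFormatError(f"wells present in data but absent from layout: {sorted(missing)}")

    channels = sorted(run["channel"].unique())
    if plate_id is None:
        plate_id = str(lay["plate"].iloc[0]) if "plate" in lay.columns else "plate1"
    layout = PlateLayout(plate_id=plate_id, wells=wells_info, channels=channels)
    od_ch = layout.od_channel

    series: dict[str, WellSeries] = {}
    for well, grp in run.groupby("well", sort=True):
        well = str(well)
        piv = grp.pivot(index="time_min", columns="channel", values="value").sort_index()
        if piv.isna().any().any():
            raise PlateFormatError(f"well {well}: missing channel values at some timepoints")
        times = piv.index.to_numpy(dtype=float)
        if len(times) > 2:
            dt = np.diff(times)
            if dt.max() > 1.05 * dt.min() + 1e-9:
                warnings.warn(
                    f"well {well}: sampling non-uniform beyond 5% tolerance; not resampled",
                    stacklevel=2,
                )
        chans = {c: piv[c].to_numpy(dtype=float) for c in piv.columns if c != od_ch}
        series[well] = WellSeries(well, times, piv[od_ch].to_numpy(dtype=float), chans)
    return Plate(layout=layout, wells=series)


def write_plate(plate: Plate, run_file, layout_file) -> None:
    """Write a plate back to long-format run + layout CSVs."""
    rows = []
    od_ch = plate.layout.od_channel
    for well in sorted(plate.wells):
        s = plate.wells[well]
        for t, v in zip(s.times, s.od):
            rows.append((well, t, od_ch, v))
        for ch, vals in s.channels.items():
            for t, v in zip(s.times, vals):
                rows.append((well, t, ch, v))
    pd.DataFrame(rows, columns=["well", "time_min", "channel", "value"]).to_csv(
        run_file, index=False
    )
    lrows = [
        (plate.plate_id, w, i.strain or "", i.role, i.replicate)
        for w, i in plate.layout.wells.items()
    ]
    pd.DataFrame(lrows, columns=["plate", "well", "strain", "role", "replicate"]).to_csv(
        layout_file, index=False
    )


# ---------------------------------------------------------------------------
# Corrections


def subtract_blanks(plate: Plate) -> Plate:
    """Subtract the per-timepoint mean of all blank wells from every well."""
    blanks = plate.layout.wells_with_role("blank")
    if not blanks:
        raise PlateFormatError("plate has no blank wells")
    out = plate.copy()
    od_mean = np.mean([plate.wells[w].od for w in blanks], axis=0)
    ch_means = {
        ch: np.mean([plate.wells[w].channels[ch] for w in blanks], axis=0)
        for ch in plate.layout.fluor_channels
    }
    for s in out.wells.values():
        s.od = s.od - od_mean
        for ch in s.channels:
            s.channels[ch] = s.channels[ch] - ch_means[ch]
    return out


def align_baselines(plate: Plate, window_min: float = 60.0) -> Plate:
    """Per strain, shift each replicate so first-hour means match the grand mean.

    Applied to OD and every fluorescence channel.  Wells without a strain
    (blanks) are left untouched; a strain with a single replicate is
    unchanged (its first-hour mean is the grand mean).
    """
    out = plate.copy()
    by_strain: dict[str, list[str]] = {}
    for w, info in plate.layout.wells.items():
        if info.strain and w in plate.wells:
            by_strain.setdefault(info.strain, []).append(w)
    for wells in by_strain.values():
        for channel in ["od"] + plate.layout.fluor_channels:
            means = []
            for w in wells:
                s = out.wells[w]
                mask = s.times <= s.times[0] + window_min
                if mask.sum() < 2:
                    raise PlateFormatError(
                        f"well {w}: series shorter than the {window_min}-min baseline window"
                    )
                vals = s.od if channel == "od" else s.channels[channel]
                means.append(vals[mask].mean())
            grand = float(np.mean(means))
            for w, m in zip(wells, means):
                s = out.wells[w]
                if channel == "od":
                    s.od = s.od + (grand - m)
                else:
                    s.channels[channel] = s.channels[channel] + (grand - m)
    return out


# ---------------------------------------------------------------------------
# Window fitting


def _fit_exponential_window(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """NLS fit of y = C0 exp(r t); returns (C0, r, R^2).

    ``t`` is relative to the window's first point.  Initialised from a
    log-linear regression on the positive values; r bounded to (0, 1] /min.
    """
    pos = y > 0
    if pos.sum() >= 2:
        coef = np.polyfit(t[pos], np.log(y[pos]), 1)
        r0 = float(np.clip(coef[0], 1e-6, 1.0))
        C00 = float(np.exp(coef[1]))
    else:
        r0, C00 = 0.01, max(y[0], 1e-6)
    popt, _ = curve_fit(
        lambda tt, c0, r: c0 * np.exp(r * tt),
        t,
        y,
        p0=[C00, r0],
        bounds=([0.0, 1e-9], [np.inf, 1.0]),
        xtol=1e-10,
        ftol=1e-10,
        maxfev=2000,
    )
    C0, r = float(popt[0]), float(popt[1])
    resid = y - C0 * np.exp(r * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return C0, r, r2


def fit_max_growth_rate(
    well: WellSeries, window_pts: int = 9, od_min: float = 0.03
) -> WellFit:
    """Maximum specific growth rate by sliding-window exponential fits.

    Every window of ``window_pts`` consecutive points whose first point has
    OD > ``od_min`` is fitted with ``C(t) = C0 exp(r t)``; the largest
    fitted ``r`` wins.  Status ``no_growth`` if no window is eligible.
    """
    if window_pts < 3:
        raise ValueError("window_pts must be >= 3")
    n = len(well.times)
    fit = WellFit(well=well.well, status="ok", window_pts=window_pts)
    eligible = [
        i for i in range(0, n - window_pts + 1) if well.od[i] > od_min
    ]
    if not eligible:
        fit.status = "no_growth"
        return fit
    n_fail = 0
    for i in eligible:
        t = well.times[i : i + window_pts] - well.times[i]
        y = well.od[i : i + window_pts]
        try:
            C0, r, r2 = _fit_exponential_window(t, y)
        except RuntimeError:
            n_fail += 1
            fit.diagnostics.append(f"window {i}: fit did not converge")
            continue
        if r <= 1e-8:
            fit.diagnostics.append(f"window {i}: non-positive rate skipped")
            continue
        fit.window_fits.append(WindowFit(start=i, C0=C0, r=r, r2=r2, t0=well.times[i]))
    if not fit.window_fits:
        fit.status = "fit_failed" if n_fail else "no_growth"
        return fit
    best = max(fit.window_fits, key=lambda wf: wf.r)
    fit.r_max, fit.C0, fit.window_index, fit.r2 = best.r, best.C0, best.start, best.r2
    return fit


def fit_max_production_rate(
    well: WellSeries, growth: WellFit, channel: str
) -> tuple[float, float]:
    """Maximum fluorescent-protein production rate for one channel.

    For every window already fitted for growth, fit ``F0`` and ``p`` in
    ``F(t) = F0 + C0 (p / r)(exp(r t) - 1)`` with ``(C0, r)`` frozen from
    that window's OD fit (a linear least-squares problem); the largest
    fitted ``p`` wins.  Near ``r = 0`` the limit ``F = F0 + C0 p t`` is
    used.  Results are recorded on ``growth`` and returned.
    """
    if growth.status != "ok":
        raise ValueError(f"well {well.well}: growth fit status is {growth.status}")
    if channel not in well.channels:
        raise KeyError(f"well {well.well}: channel {channel!r} absent")
    fvals = well.channels[channel]
    best_p, best_F0, best_idx = -np.inf, np.nan, -1
    for wf in growth.window_fits:
        i = wf.start
        t = well.times[i : i + growth.window_pts] - wf.t0
        y = fvals[i : i + growth.window_pts]
        if wf.r > 1e-9:
            basis = wf.C0 / wf.r * (np.exp(wf.r * t) - 1.0)
        else:
            basis = wf.C0 * t
        A = np.column_stack([np.ones_like(t), basis])
        (F0, p), *_ = np.linalg.lstsq(A, y, rcond=None)
        if p > best_p:
            best_p, best_F0, best_idx = float(p), float(F0), i
    growth.p_max[channel] = best_p
    growth.F0[channel] = best_F0
    growth.p_window_index[channel] = best_idx
    return best_p, best_F0


def fit_plate(
    plate: Plate,
    window_pts: int = 9,
    od_min: float = 0.03,
    exclude: set[str] | None = None,
    r2_flag: float = 0.95,
    correct: bool = True,
) -> pd.DataFrame:
    """Correct a plate and fit every non-blank well; return a fits table.

    Columns: plate, well, strain, role, replicate, r_max, C0, window_start,
    r2, p_max_<channel>, F0_<channel>, status, flagged.  ``exclude`` is a
    set of wells to drop (manual exclusion list); low-R^2 winning windows
    are flagged, never removed.
    """
    if correct:
        plate = align_baselines(subtract_blanks(plate))
    exclude = exclude or set()
    rows = []
    for well, info in plate.layout.wells.items():
        if info.role == "blank" or well in exclude or well not in plate.wells:
            continue
        series = plate.wells[well]
        gfit = fit_max_growth_rate(series, window_pts=window_pts, od_min=od_min)
        row = {
            "plate": plate.plate_id,
            "well": well,
            "strain": info.strain,
            "role": info.role,
            "replicate": info.replicate,
            "r_max": gfit.r_max,
            "C0": gfit.C0,
            "window_start": gfit.window_index,
            "r2": gfit.r2,
            "status": gfit.status,
            "flagged": bool(gfit.status == "ok" and gfit.r2 < r2_flag),
        }
        for ch in plate.layout.fluor_channels:
            if gfit.status == "ok":
                p, F0 = fit_max_production_rate(series, gfit, ch)
            else:
                p, F0 = np.nan, np.nan
            row[f"p_max_{ch}"] = p
            row[f"F0_{ch}"] = F0
        rows.append(row)
    return pd.DataFrame(rows)
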