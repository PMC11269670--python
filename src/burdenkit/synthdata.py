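"""Seeded synthetic burden-assay data with known ground truth.

Emulates the study design the analysis pipeline expects: 96-well plates
with 12 media blanks, 5 control strains and up to 23 test strains in
triplicate, OD and GFP fluorescence sampled every 10 minutes for at least
6 hours.  Optical density follows an exponential-to-saturating curve (a
generalized-logistic family whose early phase is cleanly exponential);
fluorescence accumulates as the integral of ``p * C(t)``; wells carry
additive baseline offsets, plates carry multiplicative rate effects, and
designated strains undergo stochastic mutant takeover driven by the
evolutionary-failure model, which inflates replicate-to-replicate
variance for high-burden parts.

Every quantity the pipeline estimates (growth rate, production rate,
burden, capacity-line slope, other-burden fraction) has a recorded truth
value, so recovery can be checked end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from . import evomodel
from .plate_assay import Plate, PlateLayout, WellInfo, WellSeries

__all__ = [
    "SyntheticConfig",
    "generate_plate",
    "generate_takeover_well",
    "generate_cohort",
    "CohortData",
    "plate_to_frames",
]

CONTROL_STRAINS = ("BFP1", "BFP2", "BFP3", "BFP4", "BFP5")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and truth parameters for the generator.

    Defaults mirror the assay layout (23 test strains + 5 controls in
    triplicate + 12 blanks = 96 wells; 10-min sampling for 6 h).  Rates are
    per minute; OD units are instrument OD; fluorescence is in arbitrary
    instrument units.
    """

    n_test_strains: int = 23
    n_controls: int = 5
    n_replicates: int = 3
    n_blanks: int = 12
    interval_min: float = 10.0
    duration_min: float = 360.0

    # Growth model
    r_base: float = 0.02  # no-burden specific growth rate (per min)
    od_init: float = 0.08  # inoculum OD after 5 ul overnight culture into 200 ul
    od_capacity: float = 1.5
    saturation_shape: float = 4.0  # generalized-logistic exponent; 1 = logistic
    od_blank: float = 0.04  # media background OD

    # Burden distribution for test strains: point mass at zero, a shoulder
    # of mild burden, and a tail up to the constructability bound of 45%.
    burden_zero_weight: float = 0.60
    burden_shoulder_weight: float = 0.25
    shoulder_range: tuple[float, float] = (0.01, 0.10)
    tail_range: tuple[float, float] = (0.10, 0.45)
    control_burdens: tuple[float, ...] = (0.05, 0.12, 0.20, 0.30, 0.42)

    # Expression model: true capacity line with unit slope on normalized
    # axes; production rate per cell proxy in fluorescence units/OD/min.
    capacity_slope: float = 1.0
    p_base: float = 3000.0
    fluor_blank: float = 200.0
    channel: str = "GFP"

    # Noise model.  Well-to-well variation is mostly multiplicative (path
    # length / plastic differences, `well_scale_sd`), which rate fits are
    # invariant to; the residual additive background after blank
    # subtraction (`baseline_od_sd`) is small.
    od_noise_sd: float = 0.003
    fluor_noise_sd: float = 30.0
    baseline_od_sd: float = 0.002
    baseline_fluor_sd: float = 50.0
    well_scale_sd: float = 0.02
    plate_effect_range: float = 0.15  # multiplicative, drawn U(1-x, 1+x)

    # Mutant-takeover model: strains listed here pre-grow stochastically
    # from one cell for `takeover_pregrowth_doublings` before inoculation,
    # so each replicate well starts with a random escaped-mutant fraction.
    takeover: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    takeover_pregrowth_doublings: float = 23.0
    # Cohort-level alternative: every part with burden >= takeover_min_burden
    # undergoes takeover at this mutation rate (None disables).
    takeover_mu: float | None = None
    takeover_min_burden: float = 0.25

    # Extra growth-rate reduction at unchanged GFP production, per strain.
    other_burden: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_wells = (
            (self.n_test_strains + self.n_controls) * self.n_replicates + self.n_blanks
        )
        if n_wells > 96:
            raise ValueError(f"layout needs {n_wells} wells; a plate has 96")
        if self.r_base <= 0 or self.od_init <= 0 or self.od_capacity <= 0:
            raise ValueError("rates and ODs must be positive")
        w = self.burden_zero_weight + self.burden_shoulder_weight
        if not (0 <= w <= 1):
            raise ValueError("burden mixture weights must sum to <= 1")

    def noise_free(self) -> "SyntheticConfig":
        return replace(
            self,
            od_noise_sd=0.0,
            fluor_noise_sd=0.0,
            baseline_od_sd=0.0,
            baseline_fluor_sd=0.0,
            well_scale_sd=0.0,
            plate_effect_range=0.0,
        )

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + self.interval_min / 2, self.interval_min)


def _well_names() -> list[str]:
    return [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


def _draw_burden(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    u = rng.random()
    if u < cfg.burden_zero_weight:
        return 0.0
    if u < cfg.burden_zero_weight + cfg.burden_shoulder_weight:
        return float(rng.uniform(*cfg.shoulder_range))
    return float(rng.uniform(*cfg.tail_range))


def _saturate(raw: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Map unbounded exponential growth onto a saturating OD curve."""
    nu = cfg.saturation_shape
    return raw / (1.0 + (raw / cfg.od_capacity) ** nu) ** (1.0 / nu)


def _gfp_level(burden: float, b_other: float, cfg: SyntheticConfig) -> float:
    """Normalized GFP production implied by the true capacity line.

    Expression burden moves a strain along the line; other burden reduces
    growth at unchanged GFP production.
    """
    b_ge = max(burden - b_other, 0.0)
    return max(1.0 - b_ge / cfg.capacity_slope, 0.0)


def _simulate_well(
    cfg: SyntheticConfig,
    burden: float,
    b_other: float,
    r_effect: float,
    p_effect: float,
    mutant_fraction: float,
    rng: np.random.Generator,
    substeps: int = 20,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """OD and fluorescence series for one well (before blank/baseline noise).

    A well holds an engineered subpopulation growing at ``r_base (1 - b)``
    and, if ``mutant_fraction > 0``, an escaped subpopulation growing at
    the no-burden rate and producing GFP at the no-burden level.  Both
    share the saturating capacity.
    """
    t_meas = cfg.times
    dt = cfg.interval_min / substeps
    t_fine = np.arange(0.0, t_meas[-1] + dt / 2, dt)
    r_e = cfg.r_base * (1.0 - burden) * r_effect
    r_m = cfg.r_base * r_effect
    f = mutant_fraction
    raw_e = cfg.od_init * (1.0 - f) * np.exp(r_e * t_fine)
    raw_m = cfg.od_init * f * np.exp(r_m * t_fine)
    raw = raw_e + raw_m
    od_fine = _saturate(raw, cfg)

    gfp_e = _gfp_level(burden, b_other, cfg)
    p_e = cfg.p_base * gfp_e * p_effect
    p_m = cfg.p_base * p_effect
    with np.errstate(invalid="ignore", divide="ignore"):
        w_e = np.where(raw > 0, raw_e / raw, 1.0)
    production = od_fine * (w_e * p_e + (1.0 - w_e) * p_m)
    fluor_fine = cumulative_trapezoid(production, t_fine, initial=0.0)

    idx = np.searchsorted(t_fine, t_meas)
    truth = {
        "true_r": r_e,
        "true_burden": burden,
        "true_p": p_e,
        "true_gfp_level": gfp_e,
        "true_b_other": b_other,
        "mutant_fraction": f,
    }
    return od_fine[idx], fluor_fine[idx], truth


def _pregrowth_mutant_fraction(
    b: float, mu: float, d_max: float, seed, rng_fallback=None
) -> float:
    params = evomodel.ModelParams(b=b, mu=mu, E0=1, F0=0)
    traj = evomodel.simulate_stochastic(params, d_max=d_max, seed=seed, method="hybrid")
    return float(traj.failed_fraction[-1])


def generate_plate(
    config: SyntheticConfig,
    seed,
    plate_id: str = "plate1",
    part_ids: Sequence[str] | None = None,
    burdens: Mapping[str, float] | None = None,
) -> tuple[Plate, pd.DataFrame]:
    """One synthetic plate with its truth table.

    ``part_ids`` names the test strains (defaults to partNN); ``burdens``
    optionally fixes their true burdens (otherwise drawn from the config
    mixture).  Returns the in-memory :class:`Plate` plus a per-(plate,
    strain, well) truth DataFrame; :func:`plate_to_frames` converts the
    plate to CSV-ready run/layout frames.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if part_ids is None:
        part_ids = [f"part{i:02d}" for i in range(1, config.n_test_strains + 1)]
    if len(part_ids) > config.n_test_strains:
        raise ValueError("more parts than test-strain slots")
    controls = list(CONTROL_STRAINS[: config.n_controls])

    half = config.plate_effect_range
    r_effect = float(rng.uniform(1 - half, 1 + half)) if half > 0 else 1.0
    p_effect = float(rng.uniform(1 - half, 1 + half)) if half > 0 else 1.0

    strain_burden: dict[str, float] = {}
    for pid in part_ids:
        if burdens is not None and pid in burdens:
            strain_burden[pid] = float(burdens[pid])
        elif pid in config.takeover:
            strain_burden[pid] = config.takeover[pid][0]
        else:
            strain_burden[pid] = _draw_burden(config, rng)
    for name, b in zip(controls, config.control_burdens):
        strain_burden[name] = float(b)

    names = _well_names()
    layout: dict[str, WellInfo] = {}
    series: dict[str, WellSeries] = {}
    truth_rows = []
    t = config.times
    wi = 0

    def next_well() -> str:
        nonlocal wi
        w = names[wi]
        wi += 1
        return w

    for strain in list(part_ids) + controls:
        role = "control" if strain in controls else "test"
        b = strain_burden[strain]
        b_other = float(config.other_burden.get(strain, 0.0))
        if strain in config.takeover:
            takeover_params = config.takeover[strain]
        elif (
            role == "test"
            and config.takeover_mu is not None
            and b >= config.takeover_min_burden
        ):
            takeover_params = (b, config.takeover_mu)
        else:
            takeover_params = None
        for rep in range(1, config.n_replicates + 1):
            well = next_well()
            if takeover_params is not None:
                f = _pregrowth_mutant_fraction(
                    *takeover_params, config.takeover_pregrowth_doublings, ss.spawn(1)[0]
                )
            else:
                f = 0.0
            od, fluor, truth = _simulate_well(
                config, b, b_other, r_effect, p_effect, f, rng
            )
            base_od = rng.normal(0.0, config.baseline_od_sd) if config.baseline_od_sd else 0.0
            base_fl = (
                rng.normal(0.0, config.baseline_fluor_sd) if config.baseline_fluor_sd else 0.0
            )
            scale = (
                float(np.exp(rng.normal(0.0, config.well_scale_sd)))
                if config.well_scale_sd
                else 1.0
            )
            od_meas = config.od_blank + base_od + scale * od
            fl_meas = config.fluor_blank + base_fl + scale * fluor
            if config.od_noise_sd:
                od_meas = od_meas + rng.normal(0.0, config.od_noise_sd, size=t.size)
            if config.fluor_noise_sd:
                fl_meas = fl_meas + rng.normal(0.0, config.fluor_noise_sd, size=t.size)
            layout[well] = WellInfo(strain=strain, role=role, replicate=rep)
            series[well] = WellSeries(well, t, od_meas, {config.channel: fl_meas})
            truth_rows.append(
                {
                    "plate": plate_id,
                    "well": well,
                    "strain": strain,
                    "role": role,
                    "replicate": rep,
                    "r_effect": r_effect,
                    "p_effect": p_effect,
                    "takeover": takeover_params is not None,
                    **truth,
                }
            )
    for _ in range(config.n_blanks):
        well = next_well()
        od_meas = np.full(t.size, config.od_blank)
        fl_meas = np.full(t.size, config.fluor_blank)
        if config.od_noise_sd:
            od_meas = od_meas + rng.normal(0.0, config.od_noise_sd, size=t.size)
        if config.fluor_noise_sd:
            fl_meas = fl_meas + rng.normal(0.0, config.fluor_noise_sd, size=t.size)
        layout[well] = WellInfo(strain=None, role="blank", replicate=1)
        series[well] = WellSeries(well, t, od_meas, {config.channel: fl_meas})

    od_channel = "OD600"
    plate = Plate(
        layout=PlateLayout(
            plate_id=plate_id, wells=layout, channels=[od_channel, config.channel]
        ),
        wells=series,
    )
    return plate, pd.DataFrame(truth_rows)


def plate_to_frames(plate: Plate) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format run and layout DataFrames for a plate (CSV-ready)."""
    od_ch = plate.layout.od_channel
    rows = []
    for well in sorted(plate.wells):
        s = plate.wells[well]
        for tt, v in zip(s.times, s.od):
            rows.append((well, tt, od_ch, v))
        for ch, vals in s.channels.items():
            for tt, v in zip(s.times, vals):
                rows.append((well, tt, ch, v))
    run = pd.DataFrame(rows, columns=["well", "time_min", "channel", "value"])
    lay = pd.DataFrame(
        [
            (plate.plate_id, w, i.strain or "", i.role, i.replicate)
            for w, i in plate.layout.wells.items()
        ],
        columns=["plate", "well", "strain", "role", "replicate"],
    )
    return run, lay


def generate_takeover_well(
    b: float,
    mu: float,
    seed,
    config: SyntheticConfig | None = None,
) -> tuple[WellSeries, dict]:
    """One well whose culture stochastically accumulated escape mutants.

    The strain pre-grows from a single cell for the configured number of
    doublings under the failure model with parameters ``(b, mu)``; the
    resulting mutant fraction seeds the well, whose apparent growth rate
    then drifts from ``(1 - b) r_base`` toward ``r_base`` as the
    burden-free mutants take over.  Returns the well series and its truth
    record.
    """
    cfg = config or SyntheticConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pre_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(noise_ss)
    f = _pregrowth_mutant_fraction(b, mu, cfg.takeover_pregrowth_doublings, pre_ss) if mu > 0 else 0.0
    od, fluor, truth = _simulate_well(cfg, b, 0.0, 1.0, 1.0, f, rng)
    t = cfg.times
    od_meas = cfg.od_blank + od
    fl_meas = cfg.fluor_blank + fluor
    if cfg.od_noise_sd:
        od_meas = od_meas + rng.normal(0.0, cfg.od_noise_sd, size=t.size)
    if cfg.fluor_noise_sd:
        fl_meas = fl_meas + rng.normal(0.0, cfg.fluor_noise_sd, size=t.size)
    series = WellSeries("A1", t, od_meas, {cfg.channel: fl_meas})
    return series, truth


@dataclass
class CohortData:
    """A multi-plate synthetic cohort with its combined truth table."""

    plates: list[Plate]
    truth: pd.DataFrame
    config: SyntheticConfig

    @property
    def part_truth(self) -> pd.DataFrame:
        """One row per part: true burden, GFP level and other burden."""
        t = self.truth[self.truth["role"] == "test"]
        return (
            t.groupby("strain")
            .agg(
                true_burden=("true_burden", "first"),
                true_gfp_level=("true_gfp_level", "first"),
                true_b_other=("true_b_other", "first"),
                takeover=("takeover", "first"),
            )
            .reset_index()
        )


def generate_cohort(
    config: SyntheticConfig, n_parts: int, seed, plates_per_part: int = 1
) -> CohortData:
    """A cohort of ``n_parts`` parts spread over plates of 23 test strains.

    Part burdens (and any configured other-burden / takeover behaviour) are
    drawn once at the cohort level so a part keeps one truth across all its
    plates; ``plates_per_part`` repeats each batch of parts on that many
    independent plates (replicates per part = ``plates_per_part`` times the
    per-plate replicate count).  The final plate is padded with extra
    blanks when fewer than 23 parts remain.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    part_ids = [f"part{i:03d}" for i in range(1, n_parts + 1)]
    burdens = {}
    for pid in part_ids:
        if pid in config.takeover:
            burdens[pid] = config.takeover[pid][0]
        else:
            burdens[pid] = _draw_burden(config, rng)
    plates = []
    truths = []
    per_plate = config.n_test_strains
    plate_no = 0
    for i in range(0, n_parts, per_plate):
        chunk = part_ids[i : i + per_plate]
        n_slot = len(chunk)
        pad_blanks = config.n_blanks + (per_plate - n_slot) * config.n_replicates
        cfg = replace(config, n_test_strains=n_slot, n_blanks=pad_blanks)
        for _ in range(plates_per_part):
            plate_no += 1
            plate, truth = generate_plate(
                cfg, ss.spawn(1)[0], plate_id=f"plate{plate_no}",
                part_ids=chunk, burdens=burdens,
            )
            plates.append(plate)
            truths.append(truth)
    return CohortData(plates=plates, truth=pd.concat(truths, ignore_index=True), config=config)
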