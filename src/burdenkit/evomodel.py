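"""Two-type mutation--selection model of evolutionary failure.

An engineered cell population starts from a founder carrying a burdensome
DNA construct.  Engineered cells ``E`` grow at relative rate ``1 - b``
(``b`` is the fractional growth-rate burden); loss-of-function mutants
("failed" cells ``F``) grow at relative rate 1.  Each engineered-cell
division yields a failed daughter with probability ``mu``.  In units of
the failed-cell e-folding time the deterministic dynamics are

    dE/dt = (1 - b) E - mu (1 - b) E
    dF/dt = F + mu (1 - b) E

which admit the closed-form solution used by :func:`solve_deterministic`.
Stochastic realisations (exact SSA, tau-leaping, or a hybrid of the two)
capture the waiting time for the first mutant and jackpot events that the
deterministic model averages away.

Population sizes are reported on a cell-doublings axis
``D(t) = log2[(E + F) / (E0 + F0)]`` so that cultures of different scales
are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "Trajectory",
    "ScaleSpec",
    "EnsembleSummary",
    "solve_deterministic",
    "simulate_stochastic",
    "doublings",
    "time_to_half_failure",
    "ensemble_failure_curve",
    "divisions_for_culture",
    "substitution_failure_rate",
    "effective_plasmid_rate",
]

# Largest total cell count the integer simulators will handle before the
# overflow guard triggers (comfortably inside int64).
_COUNT_CAP = 2**62

# Default population size at which the hybrid simulator hands over from the
# exact SSA to tau-leaping.  Early rare events (first mutant, jackpots) all
# happen well below this size.
DEFAULT_SSA_SWITCH = 10_000

# Default largest total population for which method="exact" is allowed.
DEFAULT_EXACT_CAP = 10_000_000


class ParameterError(ValueError):
    """Raised for invalid model or scale parameters."""


class DomainError(ValueError):
    """Raised when an operation is asked for a quantity outside its domain."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-type failure model.

    Parameters
    ----------
    b : float
        Burden: fractional reduction in the growth rate of engineered cells,
        ``0 <= b < 1``.
    mu : float
        Failure mutation rate per engineered-cell division, ``0 <= mu < 1``.
    E0, F0 : float
        Initial engineered / failed cell counts.
    """

    b: float
    mu: float
    E0: float = 1.0
    F0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.b < 1.0):
            raise ParameterError(f"burden b must satisfy 0 <= b < 1, got {self.b}")
        if not (0.0 <= self.mu < 1.0):
            raise ParameterError(f"mutation rate mu must satisfy 0 <= mu < 1, got {self.mu}")
        if self.E0 < 0 or self.F0 < 0:
            raise ParameterError("initial cell counts must be non-negative")
        if self.E0 + self.F0 <= 0:
            raise ParameterError("initial population must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time series of engineered (E) and failed (F) cell counts.

    ``times`` are in e-folding units of failed-cell growth.  ``provenance``
    is ``"deterministic"`` or ``"stochastic"``; stochastic trajectories are
    integer-valued and carry the seed they were generated with.
    """

    times: np.ndarray
    E: np.ndarray
    F: np.ndarray
    provenance: str = "deterministic"
    seed: int | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        if self.times.size == 0:
            raise DomainError("trajectory must contain at least one point")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("trajectory times must be strictly increasing")
        if np.any(self.E < 0) or np.any(self.F < 0):
            raise DomainError("cell counts must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.E + self.F

    @property
    def failed_fraction(self) -> np.ndarray:
        return self.F / self.total


@dataclass(frozen=True)
class ScaleSpec:
    """A culture scale: volume, saturation density and founding population."""

    volume_ml: float
    density_cells_per_ml: float
    start_cells: float = 1.0

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.density_cells_per_ml <= 0 or self.start_cells <= 0:
            raise ParameterError("scale parameters must be strictly positive")
        if self.volume_ml * self.density_cells_per_ml < self.start_cells:
            raise ParameterError("final cell count smaller than founding population")


@dataclass(frozen=True)
class EnsembleSummary:
    """Failure-time summary of a stochastic ensemble.

    ``half_failure_doublings`` holds the doublings at which each run first
    reached the failure threshold (runs that never failed are omitted).
    ``cdf_doublings``/``cdf`` tabulate the cumulative fraction of runs
    failed as a function of doublings.
    """

    n_runs: int
    half_failure_doublings: np.ndarray
    cdf_doublings: np.ndarray
    cdf: np.ndarray
    params: ModelParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.half_failure_doublings) > self.n_runs:
            raise DomainError("more failure times than runs")
        if np.any(np.diff(self.cdf) < 0) or np.any((self.cdf < 0) | (self.cdf > 1)):
            raise DomainError("cdf must be non-decreasing and within [0, 1]")


# ---------------------------------------------------------------------------
# Closed-form deterministic solution


def _closed_form(params: ModelParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of the linear ODE system at times ``t``."""
    t = np.asarray(t, dtype=float)
    g = (1.0 - params.b) * (1.0 - params.mu)  # net engineered growth rate
    E = params.E0 * np.exp(g * t)
    src = params.mu * (1.0 - params.b) * params.E0
    denom = g - 1.0
    if abs(denom) < 1e-12:
        # Resonant case: engineered and failed rates coincide.
        forced = src * t * np.exp(t)
    else:
        forced = src * (np.exp(g * t) - np.exp(t)) / denom
    F = params.F0 * np.exp(t) + forced
    return E, np.maximum(F, 0.0)


def _total_closed_form(params: ModelParams, t: float) -> float:
    E, F = _closed_form(params, np.array([t]))
    return float(E[0] + F[0])


def solve_deterministic(
    params: ModelParams, d_max: float, d_step: float = 0.25
) -> Trajectory:
    """Deterministic trajectory, reported on a uniform doublings grid.

    The linear system is solved in closed form and sampled at the times at
    which the total population has completed ``0, d_step, 2*d_step, ...``
    doublings, up to and including ``d_max``.
    """
    if not isinstance(params, ModelParams):
        params = ModelParams(*params)
    if d_max <= 0:
        raise DomainError(f"d_max must be positive, got {d_max}")
    from scipy.optimize import brentq

    n0 = params.E0 + params.F0
    g = (1.0 - params.b) * (1.0 - params.mu)
    d_grid = np.arange(0.0, d_max + d_step / 2, d_step)
    if d_grid[-1] < d_max:
        d_grid = np.append(d_grid, d_max)
    # Total population grows at least at rate g, so D=d is reached no later
    # than t = d ln2 / g; use that as the root bracket.
    t_hi = d_max * math.log(2.0) / g + 1.0
    times = np.empty_like(d_grid)
    times[0] = 0.0
    for i, d in enumerate(d_grid[1:], start=1):
        target = math.log(n0) + d * math.log(2.0)
        times[i] = brentq(
            lambda t: math.log(_total_closed_form(params, t)) - target,
            times[i - 1],
            t_hi,
            xtol=1e-12,
            rtol=1e-14,
        )
    E, F = _closed_form(params, times)
    return Trajectory(times=times, E=E, F=F, provenance="deterministic")


# ---------------------------------------------------------------------------
# Stochastic simulation


def _record_crossings(times, Es, Fs, t, E, F, next_idx, targets):
    """Record the state once if any doubling targets were just crossed."""
    total = E + F
    crossed = False
    while next_idx < len(targets) and total >= targets[next_idx]:
        crossed = True
        next_idx += 1
    if crossed:
        times.append(t)
        Es.append(E)
        Fs.append(F)
    return next_idx


def simulate_stochastic(
    params: ModelParams,
    d_max: float,
    seed: int | np.random.SeedSequence,
    method: str = "hybrid",
    d_step: float = 0.25,
    ssa_switch: int = DEFAULT_SSA_SWITCH,
    exact_cap: int = DEFAULT_EXACT_CAP,
    tau_epsilon: float = 0.01,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Stochastic realisation of the failure model.

    Reaction scheme: an engineered cell divides with propensity
    ``(1 - b) E``; with probability ``1 - mu`` the division yields two
    engineered cells (E += 1), otherwise one engineered and one failed cell
    (F += 1).  A failed cell divides with propensity ``F`` (F += 1).  The
    expected dynamics of this scheme are exactly the deterministic ODEs.

    ``method`` is one of:

    - ``"exact"``: Gillespie SSA throughout; refused if the final
      population would exceed ``exact_cap``.
    - ``"tau_leap"``: Poisson tau-leaping throughout with per-step relative
      population change ~``tau_epsilon``.
    - ``"hybrid"`` (default): exact SSA while the total population is below
      ``ssa_switch`` (capturing first-mutant waiting times and jackpots),
      tau-leaping above.
    """
    if not isinstance(params, ModelParams):
        params = ModelParams(*params)
    if d_max <= 0:
        raise DomainError(f"d_max must be positive, got {d_max}")
    if method not in ("exact", "tau_leap", "hybrid"):
        raise ParameterError(f"unknown method {method!r}")

    E = int(round(params.E0))
    F = int(round(params.F0))
    n0 = E + F
    final = n0 * 2.0**d_max
    if final > _COUNT_CAP:
        raise OverflowError(
            f"final population {final:.3g} exceeds the integer count cap; "
            "reduce d_max or the initial population"
        )
    if method == "exact" and final > exact_cap:
        raise ParameterError(
            f"exact SSA refused: final population {final:.3g} exceeds "
            f"exact_cap={exact_cap:.3g}; use method='tau_leap' or 'hybrid'"
        )

    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
        seed_repr = None
    else:
        rng = np.random.default_rng(seed)
        seed_repr = int(seed)

    d_grid = np.arange(0.0, d_max + d_step / 2, d_step)
    if d_grid[-1] < d_max:
        d_grid = np.append(d_grid, d_max)
    targets = n0 * 2.0**d_grid
    targets[0] = n0  # exact at the origin

    b, mu = params.b, params.mu
    one_minus_b = 1.0 - b
    t = 0.0
    times: list[float] = [0.0]
    Es: list[int] = [E]
    Fs: list[int] = [F]
    next_idx = 1
    n_events = 0

    use_ssa = method in ("exact", "hybrid")
    while next_idx < len(targets):
        total = E + F
        if use_ssa and (method == "exact" or total < ssa_switch):
            rate_e = one_minus_b * E
            rate = rate_e + F
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if rng.random() < rate_e / rate:
                if mu > 0 and rng.random() < mu:
                    F += 1
                else:
                    E += 1
            else:
                F += 1
            n_events += 1
            if n_events > max_events:
                raise RuntimeError("event cap exceeded in exact SSA phase")
        else:
            use_ssa = False
            rate = one_minus_b * E + F
            if rate <= 0:
                break
            tau = tau_epsilon * total / rate
            # Midpoint (estimated-midpoint) tau-leap: propensities evaluated
            # at the expected mid-step state, removing the O(tau) growth
            # bias of the plain Euler leap.
            e_mid = E * (1.0 + 0.5 * tau * one_minus_b * (1.0 - mu))
            f_mid = F + 0.5 * tau * (F + mu * one_minus_b * E)
            n_div_e = int(rng.poisson(one_minus_b * e_mid * tau)) if E > 0 else 0
            n_mut = int(rng.binomial(n_div_e, mu)) if (n_div_e > 0 and mu > 0) else 0
            n_div_f = int(rng.poisson(f_mid * tau)) if f_mid > 0 else 0
            E += n_div_e - n_mut
            F += n_mut + n_div_f
            t += tau
            n_events += 1
            if n_events > max_events:
                raise RuntimeError("step cap exceeded in tau-leap phase")
        next_idx = _record_crossings(times, Es, Fs, t, E, F, next_idx, targets)
        if E + F > _COUNT_CAP:
            raise OverflowError("cell count exceeded the integer count cap")

    traj = Trajectory(
        times=np.array(times),
        E=np.array(Es, dtype=float),
        F=np.array(Fs, dtype=float),
        provenance="stochastic",
        seed=seed_repr,
        method=method,
    )
    return traj


# ---------------------------------------------------------------------------
# Summaries


def doublings(traj: Trajectory, relative: bool = True) -> np.ndarray:
    """Cell doublings ``D(t) = log2(E + F)`` along a trajectory.

    By default the series is shifted so that the founding population sits at
    ``D = 0``; ``relative=False`` returns the absolute ``log2`` of Eq.-style
    total counts.
    """
    total = traj.total
    if np.any(total <= 0):
        raise DomainError("total population must be positive everywhere")
    d = np.log2(total)
    if relative:
        d = d - np.log2(total[0])
    return d


def time_to_half_failure(traj: Trajectory, threshold: float = 0.5) -> float | None:
    """Doublings at which the failed fraction first reaches ``threshold``.

    Linearly interpolates the failed fraction between stored points;
    returns ``None`` if the threshold is never reached.
    """
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must be in (0, 1)")
    frac = traj.failed_fraction
    d = doublings(traj)
    if frac[0] >= threshold:
        return float(d[0])
    idx = np.nonzero(frac >= threshold)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    f0, f1 = frac[i - 1], frac[i]
    w = (threshold - f0) / (f1 - f0)
    return float(d[i - 1] + w * (d[i] - d[i - 1]))


def ensemble_failure_curve(
    params: ModelParams,
    n_runs: int,
    d_max: float,
    seed: int,
    method: str = "hybrid",
    threshold: float = 0.5,
    d_step: float = 0.25,
    **sim_kwargs,
) -> EnsembleSummary:
    """Empirical CDF of the time to ``threshold`` failure over an ensemble.

    Runs ``n_runs`` independent stochastic simulations using seed streams
    spawned from ``seed`` and collects :func:`time_to_half_failure` per run.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    failure_times: list[float] = []
    for i, ss in enumerate(streams):
        try:
            traj = simulate_stochastic(
                params, d_max, seed=ss, method=method, d_step=d_step, **sim_kwargs
            )
            t_half = time_to_half_failure(traj, threshold)
        except Exception as exc:  # annotate with run index
            raise RuntimeError(f"stochastic run {i} failed: {exc}") from exc
        if t_half is not None:
            failure_times.append(t_half)
    ft = np.sort(np.array(failure_times))
    d_grid = np.arange(0.0, d_max + d_step / 2, d_step)
    cdf = np.searchsorted(ft, d_grid, side="right") / n_runs
    return EnsembleSummary(
        n_runs=n_runs,
        half_failure_doublings=ft,
        cdf_doublings=d_grid,
        cdf=cdf,
        params=params,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Culture-scale and mutation-rate arithmetic


def divisions_for_culture(scale: ScaleSpec) -> float:
    """Cell divisions needed to grow ``start_cells`` to a saturated culture.

    ``log2(volume_ml * density_cells_per_ml / start_cells)``; e.g. a single
    cell growing into an ~8e6-cell colony corresponds to ~23 divisions.
    """
    final = scale.volume_ml * scale.density_cells_per_ml
    if final < scale.start_cells:
        raise DomainError("final count below founding population")
    return math.log2(final / scale.start_cells)


def divisions_for_culture_rounded(scale: ScaleSpec) -> int:
    """Nearest-integer display value of :func:`divisions_for_culture`."""
    return int(round(divisions_for_culture(scale)))


def substitution_failure_rate(
    length_bp: float, lof_fraction: float, per_bp_rate: float = 5e-10
) -> float:
    """Failure rate per cell division from base substitutions alone.

    ``length_bp`` essential bases times the fraction of substitutions that
    cause loss of function times the per-base-pair substitution rate
    (default 5e-10 per generation, typical for *E. coli*).
    """
    if length_bp < 0 or per_bp_rate < 0:
        raise ParameterError("length and rate must be non-negative")
    if not (0.0 <= lof_fraction <= 1.0):
        raise ParameterError("lof_fraction must be in [0, 1]")
    return length_bp * lof_fraction * per_bp_rate


def effective_plasmid_rate(per_copy_rate: float, copy_number: int) -> float:
    """Effective failure mutation rate for a multicopy plasmid.

    Each plasmid copy is independently at risk, so the per-division rate is
    multiplied by the copy number, capped at 1 (it is a probability).
    """
    if per_copy_rate < 0:
        raise ParameterError("per_copy_rate must be non-negative")
    if not (isinstance(copy_number, (int, np.integer)) and copy_number >= 1):
        raise ParameterError("copy_number must be an integer >= 1")
    return min(1.0, per_copy_rate * copy_number)
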