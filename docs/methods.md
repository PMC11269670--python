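# Methods

## The evolutionary-failure model

Two cell types: engineered cells `E` with relative growth rate `1 − b`
(burden `b ∈ [0, 1)`) and failed (escape-mutant) cells `F` with rate 1.
Every engineered-cell division yields a failed daughter with probability
`µ ∈ [0, 1)` — one mutation class, complete relief of burden. In time
units of the failed-cell e-folding time:

    dE/dt = (1 − b)E − µ(1 − b)E,     dF/dt = F + µ(1 − b)E.

This linear system has the closed form

    E(t) = E0·e^{gt},  g = (1 − b)(1 − µ)
    F(t) = F0·e^t + µ(1 − b)E0·(e^{gt} − e^t)/(g − 1)

(with the `t·e^t` limit at `g = 1`). `solve_deterministic` evaluates this
closed form and places samples at the times where the total population
has completed each multiple of 0.25 doublings (found by bracketed
root-finding, xtol 1e-12); the doublings axis
`D(t) = log2[(E + F)/(E0 + F0)]` is reported relative to the founding
population, with the absolute `log2` available via
`doublings(..., relative=False)`. The test suite cross-checks the closed
form against an independent high-order ODE integration (DOP853,
rtol 1e-11) to a relative tolerance of 1e-8.

### Stochastic simulation

The reaction scheme is the unique minimal one whose expectation is the
ODE system: `E` divides with propensity `(1 − b)E`, yielding `2E` with
probability `1 − µ` or `E + F` with probability `µ`; `F` divides with
propensity `F`. Three integrators:

- **exact** — Gillespie SSA; refused above a configurable final
  population (default 1e7), since event counts scale with cell counts;
- **tau_leap** — Poisson leaping with step `τ = ε·N/rate` (default
  `ε = 0.01`, ~1% population change per step). Propensities are
  evaluated at the *expected mid-step state* (estimated-midpoint
  leaping): plain Euler leaping under-grows both types by `O(τ)` per
  step, and because the shortfall is larger for the faster-growing
  mutants it biases the failed fraction low by ~2% at `D = 20`; the
  midpoint variant removes this (ensemble mean within 3 SE of the ODE at
  `E0 = 1e4`, 200 runs);
- **hybrid** (default) — exact SSA while the total population is below
  1e4, tau-leaping above. The rare events that make stochastic dynamics
  differ from the ODE (the waiting time for the first mutant, early
  jackpots) all occur at small population sizes, where the SSA is both
  exact and cheap.

Counts are integers; an overflow guard rejects runs whose final
population would exceed 2^62 (56 doublings from a single cell is ~7e16,
well inside). Trajectories are recorded once per crossing of the
0.25-doubling reporting grid, so ensemble CDFs from different methods are
directly comparable. `ensemble_failure_curve` spawns independent seed
streams (`numpy.random.SeedSequence`) per run and returns the per-run
doublings to 50% failure (linearly interpolated in failed fraction
between stored points) plus the empirical CDF.

Culture-scale arithmetic is `log2(volume × density / start_cells)`:
1 cell → 8×10⁶-cell colony ≈ 22.93 (~23) divisions; colony → 4 ml at
5×10⁹ cells/ml ≈ 11.29 (~11) more. Presets for larger scales are left to
the caller since saturation densities vary by medium and process.
Mutation-rate helpers: substitution-driven failure rate =
`length × lof_fraction × 5e-10` per division; multicopy plasmids multiply
a per-copy rate by copy number, capped at 1 because `µ` is a probability.

## Plate assay fitting

Corrections follow the assay design: subtract the per-timepoint mean of
the media blanks from every channel; then, per strain and channel, shift
each replicate additively so its mean over the first hour equals the
across-replicate grand mean (this removes well-to-well background
differences between replicates; it cannot remove a background component
common to all replicates of a strain). Both corrections are applied to OD
and fluorescence alike.

Growth rates: for every window of 9 consecutive points whose first point
has (blank-corrected) OD > 0.03, fit `C(t) = C0·e^{rt}` by nonlinear
least squares (initialised from a log-linear regression on the window,
`r` bounded to (0, 1] per minute, tolerances 1e-10); the maximum fitted
`r` over windows is the well's maximum specific growth rate. OD is taken
as proportional to cell count; no calibration curve. Windows with
non-positive fitted rates are skipped and recorded in diagnostics; wells
whose winning window has R² < 0.95 are flagged, never silently dropped —
a manual exclusion list is the only removal mechanism.

Production rates: with each window's `(C0, r)` frozen from the OD fit,
`F(t) = F0 + C0(p/r)(e^{rt} − 1)` is linear in `(F0, p)` and solved by
least squares exactly (limit `F0 + C0·p·t` as `r → 0`); the maximum `p`
over windows wins. Rates are per minute; an OD660-based density channel
is supported through the layout's channel naming for strains whose
fluorophores absorb at 600 nm.

## Normalization and burden statistics

Most strains on a plate carry negligible burden, so the plate's
"no-burden" reference rate is located from the distribution of
replicate-level rates of the non-control strains: a Gaussian KDE (kernel
sd = bandwidth) evaluated on 2048 grid points spanning the data ±4
bandwidths; among strict local maxima at least 50% as high as the
tallest, the right-most is the reference (its grid bracket is refined by
bounded maximization so exact fixtures normalize to 1 to machine-level
accuracy). Every rate on the plate, controls included, is divided by the
reference.

Bandwidths are on the scale of the raw rates: 300 fluorescence
units/OD/min for production rates, and the standard growth-rate bandwidth
0.014 h⁻¹, which the pipeline converts to 0.014/60 min⁻¹ because fits
report per-minute rates. Both are configurable and instrument-scale
dependent.

Burden per measurement is `100·(1 − normalized growth rate)` percent.
Per part, one-sample one-tailed t-tests (`mean burden > threshold`) are
run against 0/10/20/30/45%; the burden-vs-0 p-values are
Benjamini–Hochberg adjusted across parts at 5% FDR (step-up, verified
against the literal definition by property test). Zero-variance samples
use the convention p = 0 if the mean strictly exceeds the threshold,
else 1. The 95% CI is t-based on the measurement mean. Parts with one
measurement are flagged untestable. `sem_burden_trend` regresses each
part's SEM on its mean burden (OLS, two-tailed slope test): escape-mutant
takeover during culture pre-growth inflates replicate variance for
high-burden parts, producing the positive trend the synthetic takeover
cohort reproduces.

## Gene-expression capacity analysis

Axes: x = normalized GFP production (the capacity monitor), y =
normalized growth rate. The expression-burden line is constrained through
the no-burden anchor (1, 1) and fitted to the control strains' per-plate
means by Deming regression: minimize `Σ (v − m·u)² / (λ + m²)` over the
slope `m` (coordinates relative to the anchor; λ = error-variance ratio,
default 1 on normalized axes), which has the closed form
`m = [Svv − λSuu + sqrt((Svv − λSuu)² + 4λSuv²)] / (2Suv)` in the second
moments about the anchor — checked against brute-force objective scans to
1e-6.

Parts annotated with GFP, YFP or the amilCP chromoprotein interfere with
the GFP readout and are excluded; parts *without any annotation record*
are excluded with a warning (an empty fluorophore list means "annotated
as fluorophore-free" and is included). Eligibility for the other-burden
test: burden significant after BH, mean burden > 10%, not excluded.

For an eligible part, location-scale t distributions are fitted by
maximum likelihood to the growth and GFP measurements (df fitted freely
but floored at 3 for samples of 10 or more; fixed at `n − 1` below that,
where the df likelihood is uninformative; the ML scale gets the standard
`sqrt(n/(n−1))` small-sample correction). The part's true position is
modelled as the independent 2-D t of the two means (scales divided by
`sqrt(n)`), and the one-tailed p-value is the Monte-Carlo mass on the
null-consistent side of the capacity line — on or above it, so p is small
when growth is reduced more than GFP production predicts. Under
on-the-line null simulations this p is approximately uniform (KS D ≈
0.05). A `halve_above` compatibility mode instead reports half the mass
on the alternative side; it is retained because that convention appears
in the field, but it caps p near 0.5 for the very parts with the
strongest other burden, so it is not the default.

Decomposition: `b_GE = 100·(1 − ŷ(x̄))` from the line at the part's mean
GFP level, `b_O = b − b_GE`; the 95% interval on `b_O/b` is a parametric
bootstrap (resampling measurement sets of the observed sizes from the
fitted t's), deliberately not truncated to [0, 1] — pure-other-burden
parts can have intervals exceeding 1. Coverage on injected-truth
simulations is ≥ 90% at nominal 95% (percentile bootstrap slack).
BH adjustment for the other-burden calls runs across eligible parts only.

## Synthetic data generator

The generator emulates the assay design itself: 96-well plates (23 test
strains + 5 controls in triplicate + 12 blanks), 10-min sampling, ≥ 6 h.
Defaults (all config fields):

- growth: no-burden rate 0.02 min⁻¹ (35-min doublings), inoculum OD 0.08
  (≈ 5 µl of saturated overnight culture into 200 µl), capacity OD 1.5,
  media blank OD 0.04;
- saturation: a generalized-logistic family
  `C = C_raw / (1 + (C_raw/K)^ν)^{1/ν}` with ν = 4, so the early phase is
  cleanly exponential before a fast rollover (ν = 1 recovers the
  logistic). This keeps the window fits' noise-free bias ≲ 0.1%, letting
  recovery checks measure noise effects rather than family mismatch;
- burden mixture for test strains: point mass at 0 (weight 0.60), mild
  shoulder U(0.01, 0.10) (0.25), tail U(0.10, 0.45) (0.15) — no burden
  above the 45% constructability bound. Control burdens
  (0.05, 0.12, 0.20, 0.30, 0.42);
- expression link: true capacity-line slope 1 on normalized axes; GFP
  production `p = p_base·(1 − b_GE/slope)` with `p_base` = 3000
  units/OD/min; injected other burden reduces growth at unchanged GFP;
- noise: additive OD sd 0.003 and fluorescence sd 30 per read; per-plate
  multiplicative rate effects U(0.85, 1.15) on growth and production;
  per-well *multiplicative* scale (lognormal, sd 2%) plus small additive
  baselines (OD sd 0.002, fluorescence sd 50). Well-to-well variation is
  modelled as mostly multiplicative (path-length/plastic differences)
  because exponential-rate fits are exactly invariant to it; large
  additive OD offsets would instead survive the first-hour alignment as
  a shared per-strain bias that coherently corrupts the t-tests — a
  failure mode of the method itself, not of its implementation — and are
  therefore not the default;
- takeover: designated strains (or all strains above a burden threshold)
  pre-grow stochastically from one cell for 23 doublings under the
  failure model; the resulting mutant fraction seeds the well with a
  second, burden-free, full-GFP subpopulation sharing the saturating
  capacity, so the apparent rate drifts from `(1 − b)·r` toward `r` and
  varies between replicates.

Fluorescence accumulates as the integral of per-subpopulation production
(`dF/dt = Σ p_i C_i`), evaluated by trapezoid on a 20× refined grid.
Cohorts draw each part's truth once; `plates_per_part` repeats parts on
independent plates for higher replicate counts. Everything is
reproducible from one `SeedSequence`.

**What the generator does not emulate** — reader optics (gain, path
length changes), evaporation and edge effects, condensation, lag-phase
and stationary-phase structure, multi-class or partial-relief mutations,
copy-number segregation. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the stated noise model, not
robustness to every artifact of real plates.

## Problem sizes used in checks

The packaged checks run ensembles of 100–200 stochastic trajectories,
single 96-well plates for rate recovery, 6-plate cohorts of 46 parts
(9 replicates each) for end-to-end recovery and capacity analysis, a
46-part null cohort for type-I control, 138-part cohorts for the
SEM-vs-burden trend, and 200–300 replicate simulations for p-value
calibration and interval coverage. The end-to-end ordering check uses
mixture weights (0.40/0.40/0.20): with the default 60% point mass at
zero, rank correlation has a ties-imposed ceiling of ~0.89 regardless of
estimation quality, so ordering is evaluated on a cohort where ordering
is defined.

## Known limitations

- The stochastic simulator guarantees distributional agreement with the
  ODE limit and exactness at small populations, not bitwise agreement
  with any particular leap-selection heuristic.
- The no-burden reference assumes most strains on a plate are
  unburdened; plates dominated by burdensome strains will normalize
  against the wrong mode.
- The other-burden p-value treats growth and GFP measurements as
  independent; replicate-level correlation between the two (shared well
  effects) is not modelled.
- Burden is an exponential-phase growth-rate statistic; lag, stationary
  survival and other fitness components are out of scope.
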