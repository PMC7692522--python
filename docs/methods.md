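# Methods

## The rationing problem

A clinic opens an epidemic season (weeks `t = 1..T`, a single incidence
peak) with a fixed stock of `W_init` single-use rapid diagnostic kits and
no resupply.  `P_t` suspected patients arrive in week `t`; each tested
patient consumes one kit, each patient visits once.  When season demand
`Σ_t P_t` exceeds `W_init`, first-come first-served exhausts the stock
mid-season, so kits must be offered probabilistically: in week `t` a
suspected patient receives a kit with *consumption rate* `r_t ∈ [0, 1]`.
The design goal is a near-constant rate that leaves neither a mid-season
dry spell nor a pile of expired-purpose kits in the final week — constant
rates also give every patient the same chance of an objective test and
yield an unbiased sample of the season for surveillance purposes.

Bookkeeping convention: `W_t` is the unused stock at the *start* of week
`t`; kits used in week `t` equal `W_t − W_{t+1}`, never exceeding `P_t` or
the stock.  Strategies activate at `t0 = 5` (configurable), i.e.
`W_5 = W_init` and the first strategy-dependent stock is `W_6`, because the
prediction-based strategy needs five weeks of data before its first fit.

## Strategies

All four rules share the recursion
`W_{t+1} = max(W_t − ⌊r_t · P_t⌋, 0)` for `t = t0..T`:

* **I (ideal)** — hindsight benchmark: `r_t = min(W_t / Σ_{s>t} P_s, 1)`,
  using the *true* future demand; rate 1 when the future sum is zero.
  Feasible only after the season ends; every other strategy is scored
  against it.
* **M (prediction-based)** — the same rule with the future demand replaced
  by `Σ_{s>t} P̂_s(t)`, the rolling forecast from data through week `t`.
  With a perfect predictor, M equals I week for week (verified exactly in
  the tests).
* **S1 (spend half)** — `W_{t+1} = W_t − min(⌊W_t/2⌋, P_t)`: aggressive
  early spending, no prediction.
* **S2 (even spread)** — `W_{t+1} = W_t − min(⌊W_t/(T−t)⌋, P_t)`: divides
  the stock over the remaining weeks, needing only an estimate of `T`; in
  the final week the whole remaining stock is offered.

For S1/S2 the reported rate is the realised share `used/P_t` (0 on
zero-patient weeks).  Consumption is deterministic expected-value flooring
by default; an optional stochastic mode draws `Binomial(P_t, r_t)` under a
seeded generator and is excluded from the headline evaluations.

## Loss metric and filling rate

A strategy X is scored by

    E^X = 1 / ((T − 5) · W_init) · Σ_{t=6..T} |W^X_t − W^I_t| ,

the time-averaged absolute gap between its stock trajectory and the ideal
one, normalised by the initial stock.  `E = 0` iff the trajectories
coincide on the scored weeks; the attainable range is `[0, 1]`.  A value
near 1/2 is characteristic of complete hoarding (or immediate exhaustion)
against an ideal trajectory that declines roughly uniformly; values above
1/2 occur when demand is concentrated just after activation, so the ideal
stock drops to zero almost immediately while a frozen strategy keeps
`|W^X_t − W^I_t| ≈ W_init` for most of the season.  S2 is particularly
exposed: whenever `W_t < T − t` its weekly share `⌊W_t/(T−t)⌋` is zero and
the stock freezes outright.  With a non-default `t0` the sum runs over
`t = t0+1..T` but the normaliser stays `(T − 5)`, keeping the default-case
formula verbatim.

Stock severity is expressed as the *filling rate* `f = W_init / Σ_t P_t`
(`f = 1`: one kit per patient).  The conversion back to a stock rounds to
the nearest integer, floor 1.  Sweeps evaluate every institution × strategy
× `f` cell, summarise per volume group with linear-interpolation quartiles
and the 1.5×IQR outlier rule, and `find_min_loss_fill` extracts the grid
argmin with an `interior` flag — an interior minimiser (`f* < 1`) is the
economically interesting regime where stocking *fewer* kits than patients
is optimal, typically seen at high-volume institutions whose curves
forecast well.

## Incidence curve and fitting

Weekly incidence is modelled with the Kermack–McKendrick single-peak bell

    P(t) = A · sech²(b·t + c) + p ,   clamped at 0,

the closed form of SIR epidemic incidence near its peak: `A` peak height
above baseline (patients/week), `b` growth/decay rate (1/week), `c ≤ 0`
phase (peak at week `−c/b`), `p ∈ [−1, 1]` small additive baseline.  The
functional form is pluggable in principle; this one reproduces the
parameter semantics of the calibration ranges below.

Fitting minimises the sum of squared residuals over weeks `1..s` under box
constraints (defaults `A ∈ (0, 3·max count]`, `b ∈ [0.1, 2]`,
`c ∈ [−10, 0]`, `p ∈ [−1, 1]`) with `scipy.optimize.least_squares`
(trust-region reflective, analytic Jacobian, zero gradient in clamped
regions).  Twenty-five fixed starting points on a coarse `(b, c)` grid —
`A` started at the observed prefix maximum, `p` at 0 — make the fit
deterministic; the lowest-cost start wins, first-found on ties.  An
all-zero prefix returns a flagged boundary fit at the smallest admissible
scale.  Rolling forecasts re-fit on weeks `1..t` for
`t = 5..T−1` and predict weeks `t+1..T`; default bounds are derived from
the full series (they play the role of ranges pre-determined from
whole-season fits across institutions).

Identifiability caveat: when `p < 0` the clamped tails are exactly zero,
and sufficiently sharp curves leave too few non-zero weeks to pin down the
quartet — several parameter sets reproduce the observations with zero
residual.  Parameter-recovery guarantees (≤ 1% relative error on noiseless
curves, machine precision in practice) therefore apply to non-clamped
(`p ≥ 0`) curves; forecasts, which only use the curve's values, are
unaffected.  The basic reproduction number implied by an underlying SIR
fit is exposed as an optional `r0_estimate` field but is not computed by
the package.

## Synthetic ensembles

Surveillance counts at institution level are generally not
redistributable, so the generator emulates a reference city-level dataset:
38 institutions over a `T = 25`-week season, split 13/13/12 by volume into
groups A/B/C.  Per group, curve parameters are drawn uniformly within the
min–max spread of published whole-season fits (2018 season); range
endpoints that sat exactly on the fitting box (`c = −10`, `p = ±1`,
`b = 2`) are pulled slightly interior (−9.5, ±0.95, 1.9) to avoid
degenerate curves.  Uniform box sampling is the least-assumptive choice
given only means and extremes, but it breaks the joint structure of real
fits: combinations such as (small `A`, large `b`) occur that no real
institution exhibited.  Two rejection rules temper this: the peak week
`−c/b` must fall in `[4, T−4]` (mid-season single peak) and the expected
season total must reach 10 patients (so filling rates are well defined;
the reference dataset's smallest institution saw 26).  Weekly counts are
the rounded curve (`noise="none"`) or Poisson draws with the curve as mean
(`noise="poisson"`, the default — the natural observation model for count
data; no noise model is prescribed by the source material).  Everything is
deterministic under the config seed.

What passing tests on these ensembles show — and what they do not: the
generator reproduces single-peak shape, group-wise scale and Poisson-level
week-to-week variation, but not reporting artifacts (holiday dips,
batching), multi-peak seasons, inter-institution correlation, or the
empirical joint distribution of curve parameters.  Ensemble-level results
(e.g. mean losses per strategy, the share of institutions with an interior
optimal filling rate) should be read as properties of this stylised
population, not of any particular city.

## Numerical conventions

* Zero denominators: empty/zero future demand ⇒ rate 1 (interpretation of
  `min(W/0⁺, 1)`), including the final week for strategy M; zero patients
  in realised-rate formulas ⇒ rate 0; S2 at `t = T` spends `min(W, P_T)`.
* `W_init` from `f`: half-up rounding, minimum 1.
* Week indices are 1-based; seasons must have `T ≥ 7` (two scored weeks).
* Ranking ties in group assignment break lexicographically by institution
  id; group sizes follow ceil-based terciles (`13/13/12` at `N = 38`).
* Group `sd` is the sample standard deviation (`n − 1`); single-member
  groups report 0 with a degeneracy flag.
* Optimiser tolerances `1e-14` (xtol/ftol/gtol), max 400 function
  evaluations per start.

## Problem sizes

The test suite and the results script use a 50-institution calibrated
ensemble (17/17/16, `T = 25`, Poisson noise) with filling-rate grid
{0.4, 0.55, 0.7, 0.85, 1.0}, 1000-instance randomised cross-checks of the
recursions against independent transcriptions (T ≤ 12, counts ≤ 20,
`W_init ≤ 50`), and a dozen noiseless generate→fit recovery round-trips —
sizes chosen so a full run completes in a few minutes on one CPU while
keeping every ensemble statistic stable at the reported precision.

## Known limitations

* Weekly resolution only; no mid-season resupply, kit expiry, multi-clinic
  transfers, multi-peak seasons, or cross-institution transmission
  structure.
* Strategy M inherits the curve's limits: seasons that peak before the
  activation week or institutions with a handful of patients per season
  give noisy fits and can push its loss far above typical values.
* The loss compares stock *trajectories*; it does not weigh clinical
  consequences of an untested patient, and an "excess reserve" that the
  metric penalises could be desirable in practice.
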