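# Methods

## Model structure

The population is projected in daily steps through seven compartments:
non-diapausing eggs (Egg), tagged eggs (Egg\*), diapausing eggs (Egg°),
larvae, pupae, naive (nulliparous) females and parous adult females. Within a
day the update order is fixed: (1) breeding-site capacity, (2) immature
density, (3) life-history rates, (4) season indicators and the tagged
fraction, (5) cohort development, (6) survival of the non-queued stocks
(diapausing eggs, adults), (7) oviposition. All flows are evaluated from the
start-of-day state, so one step is exactly the projection `n[t+1] = G + M·n[t]`;
the matrix form itself is order-free but a discrete implementation is not,
and the in-suite dense oracle uses the same ordering.

Development is age-structured. Each of Egg, Egg\*, Larva, Pupa and Naive
keeps a queue of daily cohorts carrying (size, accumulated development
fraction). A day adds `1/d_t` to every cohort and multiplies its size by the
day's survival; cohorts reaching a fraction of 1 progress. The realized
duration is therefore the infimum rule `d_total = inf{n : Σ_{t≤n} 1/d_t ≥ 1}`
and the surviving mass is `Π_{t≤d_total} p_t`, with survival applied on the
progression day as well. Tagged eggs develop exactly like normal eggs
(`d1, p1`) but become diapausing eggs on completion. Naive females develop
with duration `t_bm(T_a)` and survive at the adult rate `p4`; completed
pupal cohorts contribute half their mass to naive females (1:1 sex ratio,
males are not followed).

Two conventions are worth stating explicitly because the matrix row for
diapausing eggs is often written loosely:

* diapausing eggs survive at the daily rate `p0(T_a)` and, when the season is
  favourable, a fraction `p_n` of the survivors hatches:
  `Egg°[t+1] = p0·(1 − I_fav·p_n)·Egg°[t] + Egg*_dev`, with
  `I_fav·p_n·p0·Egg°[t]` entering the larval queue;
* "eggs laid" (the surveillance observable) counts oviposition inflows only
  (normal + tagged). Counting Egg\*→Egg° conversions as well would re-count
  eggs already counted when laid; a flag (`count_diapause_conversions`)
  exists for sensitivity checks.

## Environmental dependence and parameters

The 48-entry parameter vector groups as: four development-time quadratics
(egg, larva, pupa, blood-meal; 12 entries), a fecundity quadratic (3), a
linear diapausing-egg survival (2), four two-sided survival sigmoids
(`p_max, T_low, T_high`, one shared slope each; 16), density dependence
(`α_a..α_e` for the development inflation `max(1, α_d μ^α_e τ(T_w))` with
`τ(T_w) = α_a + α_b T_w + α_c T_w²`, plus the survival decay shape `α_LD`; 6),
breeding site (`α_pdens, α_dprec, α_evap`; 3), diapause switching
(`T_crt, CPP, p_s, p_n`; 4), the water-temperature offset `Δ_T` (1) and the
introduced diapausing-egg stock `E0_init` (1).

Design choices where the families were open:

* the two-sided sigmoid is the product of a rising and a falling logistic;
  the canonical vector ties the two slopes (the class accepts distinct ones);
* density-dependent immature survival `p_LD = exp(−α_LD μ)` is the simplest
  monotone single-parameter family on [0, 1] and sits behind the operation
  contract, so it can be swapped;
* the adult lifespan under fixed daily mortality is the geometric expectation
  `1/(1−p4)` (used by `daily_fecundity`); the continuous-hazard alternative
  `−1/ln p4` is available via `mean_lifespan(..., "continuous")`;
* durations are floored at 1 day to keep the `1/d` rates bounded at extreme
  temperatures;
* a cohort progresses when its accumulated fraction reaches `1 − 1e−9`; the
  slack makes `d` days at a constant rate `1/d` complete on day `d` despite
  binary rounding;
* the density index is capped at `μ_max = 10³` (relevant only when capacity
  collapses with immatures present) to keep `μ^α_e` finite; `μ := 0` when
  both capacity and immatures are zero.

Reference values (the defaults, also the prior means) describe a temperate
strain at the per-ovitrap habitat scale: development minima of a few days
near 25–30 °C, adult survival anchored at thermal limits −3 °C and 37.5 °C
(prior sd 1 °C each), fecundity peaking ~10–14 eggs/day and staying positive
down to ~11 °C, diapause entry at `T_crt = 16 °C`, `CPP = 12.5 h`. The
switching thresholds were placed so that induction overlaps the autumn laying
window — with a colder threshold the fecundity curve is already zero when the
unfavourable season starts, no tagged eggs are ever laid, and the diapause
pathway is vacuously inactive (no overwintering egg bank). Under the
defaults a simulated temperate winter holds diapausing eggs only, with
larvae and adults at effectively zero — the overwintering structure the model
is built around. `Δ_T` has prior mean 0 (sd 3 °C). The breeding-site scale
is "per ovitrap-equivalent habitat", so simulated egg counts compare directly
to eggs-per-trap surveillance without a separate scaling parameter. `B` is
initialized at 0; the burn-in year absorbs the transient, and the capacity
normalizer makes `K` exact from day 1 under constant inputs.

Season memory: an unfavourable season begins on the first day with both
`T_a < T_crt` and photoperiod < CPP, and ends only on a day with both above.
On mixed days inside a season tagging pauses (normal eggs are laid) but the
season persists; the tagging ramp `p_dp` runs on calendar days since onset by
default, with a variant (`ramp_counts_unfav_only`) that counts only
unfavourable days. After a mid-winter warm spell terminates a season, a new
onset restarts the ramp.

Photoperiod uses the Forsythe et al. (1995) daylength model with the
sun-centre daylength coefficient `p = 0°` (the default convention of the
standard geospatial daylength routine); the coefficient is exposed, and the
suite cross-checks against a Spencer-declination oracle to < 0.05 h.

## Calibration

For province *r* and 14-day window *ω* the observable `y(r, ω, θ)` is the
summed oviposition inflow over the window, averaged over the province's grid
cells. The likelihood has Gaussian terms on the window means (sd = reported
SEM) and on consecutive same-year differences (sd = the pooled SEM of the two
windows); the first window of each year carries no difference term. The
objective `f(θ)` is half the squared Mahalanobis distance of the stacked
prior and data residuals (prior covariance block-diagonal by fitted curve),
i.e. the negative log posterior up to a constant; out-of-bounds proposals
score +∞.

The search runs several adaptive Metropolis chains over a geometric annealing
ladder (`T_high → T_low`, cycled per phase; acceptance
`min{1, exp[(f−f′)/T_ann]}`, which is Metropolis–Hastings at `T_ann = 1`).
Proposals use per-dimension scales adapted toward a 30% acceptance rate,
switching to the empirical covariance of accepted history (scaled `2.38²/d`)
once enough points accumulate. Chain starts alternate between narrow
(0.1 prior sd) and full-prior-sd spreads around the supplied centre so that
separated basins are reachable. Chain bests are descended to their local
minimizers (a guarded Nelder–Mead polish) before deduplication by a
normalized distance, so modes are compared at their floors. Each surviving
mode is then sampled by a fixed-temperature chain (`T_ann = 10`, 100 thinned
draws); on a Gaussian toy objective this widens the sample covariance by the
temperature factor, which the suite asserts.

Mode masses follow the importance-sampling estimator
`mass(Θ) ∝ (1/N_Θ) Σ_i exp(−f(θ_i)/T_tol) / Pr(θ_i|S)` with `Pr(θ|S)` the
equal-weight mixture of per-mode Gaussian approximations (population
covariance, ridge-stabilized — duplication-invariant by construction). Only
normalized masses are exposed; at `T_tol = 1` mass ratios equal Bayes
factors. Sensitivity is `H = diag(θ̂)ᵀ Σ⁻¹ diag(θ̂)` with a logged ridge if
the mode covariance is numerically singular.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions used by the tests and the
reproduction script: daily temperature as an annual sinusoid (coldest
mid-January) plus iid Gaussian noise; precipitation as a
Bernoulli(wet-day) × Exponential(mean) mixture; constant human population
density; photoperiod from the real calendar. Surveillance is biweekly
May–October windows; the reported mean is the model observable plus
`N(0, noise_sd)` (negative draws clamped to zero and logged) and the reported
SEM is `noise_sd/√n_traps`. Note the deliberate asymmetry: the sd applied to
the mean is `noise_sd` itself while the table reports the smaller per-trap
SEM, so the likelihood is conservative (overconfident) relative to the true
noise — a stress on the calibration rather than a favour.

The recovery experiment uses two climatically distinct provinces (lat 44.5,
mean 13 °C, amplitude 11 °C; lat 42.0, mean 16 °C, amplitude 9 °C), three
simulated years (establishment year + two surveyed seasons), 25 traps and
`noise_sd = 0.2` eggs/trap. Only `T_crt`, `CPP` and `p_n` are freed (the
remaining 45 stay at the prior mean, which equals the generating truth); the
prior means of the free parameters are offset (−2 °C, −0.5 h) so the data
must pull them back. The budget is ~1.5×10⁴ objective evaluations — a
deliberately scaled-down design that completes in a couple of minutes on one
CPU.

What passing these tests does **not** show about real data: the synthetic
drivers have no autocorrelated weather regimes, no spatial heterogeneity
within a province beyond one cell, no trap-level variation or missing
collections, and the noise matches the likelihood family by construction.
Real calibrations face model misfit between a 25-km grid average and
micro-habitats, which these conditions cannot probe.

## Numerical implementation

The projection is implemented twice: an explicit object route
(`CohortQueue`/`PopulationState`/`step`) that is the contract surface and
reference, and a numba-compiled kernel over flat arrays used by `simulate`
and the calibration loop (~0.5 ms per simulated year). The suite asserts
bit-level agreement of the two routes over multi-year runs and agreement of
the reference route with an independent dense `G + M·n` re-implementation to
1e−10 relative (with an absolute floor far below one individual absorbing
the dense route's own cancellation residue). Cohorts below 1e−30 are dropped
during compaction.

Climate grids are read through xarray's NetCDF3 (scipy) engine with kelvin
auto-conversion; missing values propagate as NaN and a caller-supplied
land/population mask predicate selects cells. All precipitation is treated
as rainfall, and no downscaling or bias correction is attempted.

## Known limitations

* No age-dependent adult mortality (the cohort machinery would support it).
* No migration between cells; provinces are independent habitats.
* The breeding-site model cannot be calibrated against direct observations
  (none exist in surveillance datasets); its parameters are identified only
  through the population dynamics.
* Mode masses depend on the Gaussian approximation of each mode's samples;
  strongly curved basins would need a richer sampling density.
* Recovery accuracy is realization-dependent: with weaker identifiability
  (e.g. diapause thresholds outside the active laying season) the posterior
  can develop near-degenerate basins in which temperature- and
  photoperiod-controlled switching trade off — the same trade-off reported
  for field calibrations.
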