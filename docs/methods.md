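# Methods

## The estimation problem

Recreational fisheries managers need to separate fishing mortality (F)
from natural mortality (M). For large lake fish this package combines two
information sources: high-reward anchor tags, whose near-certain reporting
makes every angler recapture an observed event, and fixed-station acoustic
telemetry, whose repeated detections distinguish a live unreported fish
from a dead one. The data are reduced to seasonal encounter histories and
fitted with an individual state-space Cormack–Jolly–Seber (CJS) survival
model; closed-form transforms then convert the fitted seasonal
probabilities into annual interval probabilities, instantaneous rates,
catchability and density.

## State-space model

Time is discretised into calendar quarters (winter Jan–Mar, spring
Apr–Jun, summer Jul–Sep, autumn Oct–Dec). Fish `i` enters at its release
period `f_i` alive (`z[i, f_i] = 1`) and thereafter

    z[i, t+1] ~ Bernoulli(z[i, t] * phi[i, t])        survival
    y[i, t]   ~ Bernoulli(z[i, t] * rho[i, t])        reported recapture
    m[i, t]   ~ Bernoulli(z[i, t] * T[i, t] * delta[i, t])   detected moving
    x[i, t]   ~ Bernoulli(z[i, t] * S[i, t] * kappa[i, t])   spawning

where `T` flags a transmitter active for the whole period and `S` the
species' spawning season (summer for Bull Trout, spring for Rainbow
Trout). Each probability is logit-linear:

    logit(phi)   = b_phi0 + b_phix * x + b_phiY * Y
    logit(rho)   = b_rho0 + b_rhoY * Y
    logit(delta) = b_d0   + b_dS * S  + b_dY * Y
    logit(kappa) = b_k0   + b_kL * L  + b_kY * Y

with `L = (FL - 600) / 100` the rescaled fork length, grown along a
seasonal Von Bertalanffy curve `FL(t) = FL(f) + (L_inf - FL(f)) *
(1 - exp(-0.25 k (t - f)))` (`L_inf` = 1,000 mm; k = 0.13 for Bull Trout,
0.19 for Rainbow Trout), and `Y` the standardised calendar year.

Because the spawning state enters survival only in the spawning-season
period, a spawner's annual survival is `phi_ns^3 * phi_sp`: the survival
cost of spawning is paid once per year. Histories are conditioned on
release — observations in the release period are not modelled, and `T` is
structurally 0 there — and a fish is censored after the period of a
reported recapture (same-period movement and spawning observations are
retained).

Seven of the eleven coefficients (all but the four intercepts) carry
spike-and-slab selection indicators:

    gamma ~ Bernoulli(1/2)
    beta  ~ gamma * Normal(0, 3) + (1 - gamma) * Normal(0, 0.03)

The posterior mean of `gamma` is the selection probability of the effect;
the spike sd of 0.03 pins an excluded coefficient at effectively zero
without removing it from the linear predictor.

## Sampling

`CJSModel.fit` runs independent chains (default 5 × 1e5 iterations, first
half discarded, thinned to 10,000 total draws) alternating:

1. **Alive states** by forward-filtering backward-sampling per fish. The
   2-state chain (alive/absorbing dead) is filtered with latent spawning
   states collapsed out of the transition — the effective spawning-season
   survival is the mixture `kappa * phi(x=1) + (1-kappa) * phi(x=0)` —
   which both matches the exact marginal likelihood and avoids the sticky
   configuration where a sampled `x = 1` would forbid death.
2. **Unobserved spawning states** from their Bernoulli full conditionals
   given the alive path (observed states, available where `T = 1` in a
   spawning-season period, are data).
3. **Coefficients** by single-site random-walk Metropolis. Each
   coefficient touches exactly one likelihood block (survival, recapture,
   movement or spawning), so proposals re-evaluate only that block on
   pre-compressed observation vectors. Proposal scales adapt toward ~35%
   acceptance during burn-in and are frozen afterwards, preserving
   detailed balance in the retained half.
4. **Indicators** by exact Gibbs given the coefficient (slab vs spike
   density ratio), followed by a joint flip move that proposes the
   opposite indicator together with a fresh coefficient drawn from the
   corresponding prior component. Prior and proposal cancel, leaving a
   pure likelihood-ratio acceptance; this move is what carries a
   coefficient between the spike and a distant slab mode.

Chains are seeded from per-chain substreams of the master seed
(`numpy.random.SeedSequence`), so a fit is fully reproducible. Chains are
initialised at `0.1 ×` draws from the slab prior, indicators at fair coin
flips, alive states all-alive.

`marginal_loglik` implements the exact observed-data likelihood by the
same forward recursion without sampling. It is never used by the sampler;
it exists as the independent oracle — tests verify it against brute-force
enumeration over all latent configurations (machine precision, ≤3 fish ×
≤4 periods) and verify the MCMC against a dense-grid posterior computed
from it.

### Diagnostics and summaries

Convergence uses the classic Gelman–Rubin between/within form; a fit is
flagged converged when every free parameter has R-hat ≤ 1.05 (all-equal
constant chains count as 1.0 by convention — relevant for indicators stuck
at 1). Prior vagueness is assessed by refitting with the slab widened to
sd 6 (`PriorConfig.sensitivity()`; whether the spike widens too is a
switch, off by default) and computing R-hat with each model's pooled draws
as one chain, ≤ 1.2 taken as insensitive. Summary tables report the
posterior mean, central 95% credible interval, SD, percent relative error
(half-interval width over |mean| × 100) and a two-sided tail-probability
significance floored at `1/n_draws` (0.0001 at the default 10,000 draws).
Derived quantities are computed per draw and summarised afterwards — the
posterior mean of the transform, not the transform of the mean.

## Telemetry reduction

The prep pipeline applies, in order: (1) discard receiver-hours with ≤ 2
detections of a fish (acoustic collisions) or beyond the transmitter's
expected tag life; (2) collapse to one lake section per fish-day, resolved
by most detections, then fewest receivers, then smallest area (sectional
areas are unique, so the cascade always resolves); (3) exclude fish not
detected after release + 30 days, or only ever detected in one section, as
post-release mortalities; (4) infer spawning — Bull Trout by a ≥ 4-week
detection hiatus overlapping August–September with detections on both
sides, Rainbow Trout by an April–May detection at the monitored outflow
spawning section or a ≥ 3-week April–May hiatus bracketed by detections in the
uppermost lake sections; by default a hiatus qualifies when its total
length reaches the threshold and it overlaps the window at all
(`strict_containment` requires the overlap itself to reach the threshold);
(5) assemble the seasonal matrices. A gap is the run of days strictly
between consecutive daily assignments. Monitoring (`T = 1`) requires the
transmitter active for the entire period, so a mid-period tag death gives
an unmonitored period rather than a partially observed one. The
emigration audit tabulates fish last detected ≥ 120 days before
transmitter expiry and never recaptured, by final section and season.

## Synthetic data

`simulate_encounters` draws histories directly from the model above, with
default design sizes mirroring the motivating study: ~88 + ~149 fish
released 2008–2013, transmitters (tag lives 455/830/1,239 days) through
2011, anchor-only cohorts in 2012–2013, fork lengths ~ Normal(650, 80)
truncated to [500, 980] mm, and generating coefficients of study-like
magnitude (e.g. seasonal survival intercept ~2.7, recapture intercept
~ -3.1). `simulate_telemetry` renders such a history as raw hourly
detections: one section per day, within-period movement as a mid-period
section switch, spawning as the species-appropriate planted hiatus (Bull
Trout: silent Jul 26 – Aug 31; Rainbow Trout: an outflow-section visit or
an April–May hiatus bracketed in the upper lake, entirely inside the
period so recovery does not depend on later survival), plus noise rows of
≤ 2 detections, post-tag-life rows, 7% multi-section days, and planted
post-release failures that are silent or single-section from day 0.

Two generator choices exist purely to give the reduction rules an exact
ground truth: non-planted fish are conditioned to survive their first
transition, and every retained fish visits a second section during its
release period. Without them, a natural death in the first winter is
observationally identical to a post-release failure (a genuine confound of
the 30-day rule, not an artefact). The encounter-level generator used for
inference tests applies no such conditioning.

What the generator does *not* emulate: receiver range and coverage gaps
(every section is detectable), temperature/behaviour-driven detectability,
tag shedding, non-reporting anglers, movement that is actually spatially
autocorrelated. Passing tests therefore demonstrate correctness of the
reduction rules and estimator calibration under the model's own
assumptions, not robustness to their violation in field data.

## Derived rates

With seasonal probabilities `p`, annual interval values are `p^4`
(survival) and `1 - (1-p)^4` (recapture); spawners use `phi_ns^3 *
phi_sp`. Instantaneous rates are `F = -log(1 - rho_annual)` and `M =
-log(phi_annual)`; effective interval fishing mortality discounts released
fish by `rho_annual * (1 - release_rate)`. Catchability is `q = rho / E`
with effort `E` in angler-hr ha⁻¹ yr⁻¹ (the study constants: 189,457
angler hours on 38,800 ha, i.e. E = 4.88), and density implied by a known
catch `C` is `D = (C / rho) / area`. Two empirical M estimators
(`4.899 t_max^-0.916` and `4.188 k^0.73 L_inf^-0.33`) and a meta-analytic
hyperstability curve `q = exp(-0.14 E / (1 + 0.35 D)) / E` are provided
for comparison. Production reporting applies all transforms per posterior
draw; the plug-in forms can differ from per-draw posterior means in the
last digit (Jensen's inequality), which is why worked-example tolerances
are ±0.01.

## Tag loss

Double-tagged fish that shed both anchor tags are unobservable at
recapture, so retention counts follow a binomial truncated at zero
retained tags: P(both) = (1-p)/(1+p), P(exactly one) = 2p/(1+p). With a
Uniform(0,1) prior the posterior is one-dimensional; `TagLossModel` offers
exact quadrature and a random-walk MCMC sampler (cross-checked to three
decimals), reporting the per-tag probability `p` and the both-tags
probability `p²`.

## Numerical choices and limitations

* Year standardisation uses the distinct calendar years, equally weighted,
  with the sample (n−1) SD; `ddof` is exposed because the convention is
  not identifiable from published values. A single-year calendar sets
  Y ≡ 0.
* Probabilities are evaluated through log-sigmoid forms
  (`-log(1+exp(∓eta))`), so extreme linear predictors cannot overflow;
  the forward filter normalises per step.
* An observation history with zero likelihood (e.g. a positive observation
  at a period the latents make impossible) raises rather than returning
  −inf from the filter.
* Degenerate fits: a fish whose window is a single period contributes
  nothing; data with no modelled observations return the prior (verified
  by a dedicated test).
* Test and acceptance runs use scaled-down chains (e.g. 5 × 3,000
  iterations for the 200-fish recovery study, 2 × 1,500 for the
  20-replicate calibration study); the package default remains 5 × 1e5
  thinned to 10,000 draws.
* The sampler keeps latent draws internal and retains only coefficients
  and indicators; per-fish survival trajectories can be reconstructed by
  rerunning the filter at retained draws if needed.
* Known limitations: spawning Bull Trout that die before returning to the
  lake are scored as non-spawning in-lake mortalities (biasing spawner M
  low and non-spawner M high); reliance on a single capture method leaves
  individual catchability heterogeneity untestable; effort and catch are
  treated as known constants, so derived q and D carry no creel-survey
  uncertainty.
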