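# tagtelem

Survival, fishing and natural mortality estimation for large lake fish
from combined **high-reward anchor tagging** and **fixed-station acoustic
telemetry**.

Separating fishing mortality (F) from natural mortality (M) is a central
problem in managing recreational fisheries. When every recapture carries a
$100 reward tag, angler returns can be treated as fully reported events;
when the same fish carries an acoustic transmitter, repeated detections
distinguish a live unreported fish from a dead one. `tagtelem` implements
the full analysis for this design:

* **Telemetry reduction** — hourly detection filtering (≤ 2 detections per
  receiver-hour and post-tag-life records discarded), daily section
  assignment with a most-detections / fewest-receivers / smallest-area
  tie-break cascade, 30-day post-release mortality screening,
  species-specific spawning inference from detection hiatuses, and
  seasonal encounter-history matrices.
* **An individual state-space Cormack–Jolly–Seber model** with latent
  alive states `z[i,t+1] ~ Bern(z[i,t]·φ[i,t])` and observation layers for
  angler recapture (ρ), movement detection (δ) and spawning (κ), all
  logit-linear in spawning state, Von Bertalanffy fork length and
  standardised year. Model selection uses spike-and-slab indicator
  variables: `β ~ γ·N(0,3) + (1−γ)·N(0,0.03)`, `γ ~ Bern(½)`, so the
  posterior mean of `γ` is the inclusion probability of each effect. The
  sampler (forward-filtering backward-sampling for `z`, Gibbs for latent
  spawning states and indicators, adaptive Metropolis for coefficients) is
  tested against exact enumeration and grid posteriors.
* **Derived rates** — annual interval conversions (`p⁴`,
  `1−(1−p)⁴`, spawner survival `φ_ns³·φ_sp`), instantaneous rates
  `F = −log(1−ρ)` and `M = −log(φ)`, catchability `q = ρ/E`, density
  `D = (C/ρ)/area`, empirical M estimators and a hyperstability curve.
* **A zero-truncated binomial tag-loss model** for double-tagged
  recaptures (fish that shed both tags are unobservable).
* **A synthetic-data generator** at two fidelity levels (encounter
  histories and raw hourly telemetry with planted ground truth), so the
  entire pipeline is testable without any external data.

## Worked example

Simulate a study-sized cohort (200 fish, six years, 24 seasonal periods),
fit the model, and derive the fisheries quantities:

```python
import numpy as np
from tagtelem import CJSModel, MCMCConfig, rates
from tagtelem.simulate import simulate_encounters, small_design

design = small_design(n_fish=200, n_years=6, seed=9)
data, truth = simulate_encounters(design)

result = CJSModel(data).fit(
    MCMCConfig(n_chains=4, n_iterations=2000, n_retain_total=2000, seed=1))
print(result.summary().round(3))

rho = result.probability_draws("recapture", year=2011)   # per-draw seasonal prob.
annual = rates.annual_interval(rho, "recapture")
F = rates.instantaneous_F(annual)
print("annual recapture: %.2f [%.2f, %.2f]" % (annual.mean(), *np.quantile(annual, [.025, .975])))
print("F: %.2f [%.2f, %.2f]" % (F.mean(), *np.quantile(F, [.025, .975])))
```

Output (abridged):

```
                     estimate  lower  upper     sd   error  significance
surv_intercept          2.844  2.642  3.047  0.105   7.114         0.000
surv_year              -0.822 -1.090 -0.564  0.134  32.032         0.000
recap_intercept        -3.089 -3.328 -2.856  0.119   7.628         0.000
move_intercept          2.336  2.148  2.521  0.095   7.980         0.000
move_spawn_season      -2.151 -2.399 -1.917  0.128  11.204         0.000
spawn_length            1.288  0.029  2.186  0.487  83.747         0.027
g_surv_year             1.000  1.000  1.000  0.000   0.000         0.000
g_move_spawn_season     1.000  1.000  1.000  0.000   0.000         0.000
g_spawn_length          0.966  0.000  1.000  0.181  51.760         0.000
g_move_year             0.034  0.000  1.000  0.183 1449.275        0.000
annual recapture: 0.17 [0.13, 0.21]
F: 0.18 [0.14, 0.24]
```

The fit recovers the generating coefficients (surv_intercept 2.73,
recap_intercept −3.07, move_spawn_season −2.40, …) within two posterior
SDs; the selection indicators identify exactly the effects that were
simulated as non-zero (year trend in survival, spawning-season drop in
movement, length effect on spawning) and shrink the absent ones. A
seasonal recapture probability of ~0.045 annualises to 0.17, i.e. an
instantaneous fishing mortality of ~0.18 yr⁻¹ if all recaptures are
harvested.

The tag-loss model on its own:

```bash
tagtelem tagloss --double 18 --single 7
#            estimate   lower   upper      sd
# p            0.1834  0.0802  0.3241  0.0629
# p_both       0.0376  0.0064  0.1050  0.0261
```

Eighteen double-tag and seven single-tag returns imply an ~18% per-tag
loss probability and ~4% probability of losing both tags.

## Command line

`simulate`, `prep`, `fit`, `summarize`, `derive`, `tagloss` and `all`
chain the stages over plain CSV files; see `tagtelem --help`. All
randomness flows from a single master seed, so reruns are byte-identical.

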