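# Methods

## Observation model

Tumour i, measured for the j-th time, has volume V_{i,j} (cm³) at time
t_{i,j} (days since that tumour's first capture, so t_{i,1} = 0). Each
growth law V(t; θ, t₀) is anchored by V(t₀) = V₀ with V₀ = 0.125 cm³ —
an estimate of the minimum visible tumour (a 0.5 cm cube) — and a latent
per-tumour anchor time t_{i,0}, which may be negative (the tumour passed V₀
before first capture). Log-volumes are Gaussian about the log growth
curve with shared variance ε:

log V_{i,j} ~ N( log V(t_{i,j}; θ, t_{i,0}), ε ).

The lognormal error is multiplicative on volume and absorbs both calliper
error and biological rate variation between tumours; it also guarantees
positive predicted volumes on the log scale where fitting happens.

Assumptions worth stating plainly: a single θ per cohort split (no
per-tumour random effects), a single ε shared by all tumours and times,
independence across measurements given the curve, and ignorable censoring
(mortality removes observations but does not enter the likelihood).

## Fitting

Maximum likelihood by nested optimisation:

* **Outer**: bounded Nelder–Mead over log θ from ≥ 20 Latin-hypercube
  starts (seeded; deterministic). Convergence tolerances 1e-10 on the
  objective and coordinates.
* **Inner (t₀ profile)**: for the exponential law the profile is closed
  form, t₀ = mean_j [t_j − (log V_j − log V₀)/r]. Otherwise each tumour's
  anchor is profiled on a coarse (10-day) then fine (0.1-day) grid over
  [−3000, +3000] days with parabolic interpolation, vectorised across the
  cohort; the bracket reflects the epidemic's start (~10 years of data).
  Anchors placing any observation outside a law's domain score +∞ and are
  never selected; a tumour with no valid anchor rejects that θ outright
  (log-likelihood −∞). At the optimum every anchor is re-polished by
  bounded Brent minimisation. Single-measurement series are solved exactly
  by inverting the growth curve through their one point (zero residual).
* **ε profile**: closed form, ε̂ = mean squared log-residual, floored at
  1e-8 so noise-free fixtures stay finite.

Parameter counting for AICc: k = |θ| only (logistic 2, exponential 1).
The t_{i,0} and ε are profiled nuisances; counting them would make every
model's k grow with the cohort and break the comparison. n is the number
of measurements in the split being fitted; ties in a ΔAICc column break
toward the law with fewer parameters.

Singleton series (one measurement) are kept by default: after profiling
they contribute zero residual and affect only n. The stricter
`min_points_per_tumour=2` is a config switch. Known consequence: ε̂ is
biased low by roughly (n − m)/n (m = number of tumours) because each
profiled anchor absorbs one residual degree of freedom.

Parameter bounds (natural scale): r, rates ∈ [1e-4, 1]/day; K ∈ [1, 1e5]
cm³; Mendelsohn b ∈ [0.05, 3] with b = 1 excluded (degenerates to
exponential); ρ ∈ [1e-5, 0.5]/day; α ∈ [1e-4, 10], β ∈ [1e-4, 1]/day.
Only r and K have published estimates for this system; the rest are
package choices wide enough not to bind in practice.

## Posterior sampling

No standard prescription exists for credible intervals in this profiled
setting, so the package makes its own choices and records them here. The
posterior is over θ only, with t₀ profiled out and ε handled in one of two
ways:

* default (`df_adjusted=True`): ε is integrated out under a Jeffreys prior
  using the residual degrees of freedom ν = n − m, giving a Student-like
  target ∝ SS(θ)^(−ν/2). The plain plug-in profile (ε̂ = SS/n) treats the
  variance as estimated from n residuals when only n − m are free; on
  singleton-heavy cohorts that over-sharpens the posterior badly (measured
  55% coverage of true r at nominal 95% on default synthetic cohorts,
  restored to ~97% by the adjustment).
* `df_adjusted=False` reproduces the plain profile posterior.

Priors are log-uniform (flat in log θ) over the parameter bounds. The
sampler is adaptive random-walk Metropolis on log θ: 4 chains (default)
jittered around the MLE, per-coordinate proposal scale adapted toward ~30%
acceptance during burn-in only, split-chain potential scale reduction
(R-hat) reported and warned about above 1.05; samples are returned either
way. Central credible intervals are equal-tailed empirical quantiles.

Joint sampling of (θ, t₀, ε) was considered and rejected: 60+ latent
anchors make the chain slow to mix for no gain on the quantities reported
(r, K).

## Permutation tests

Group differences in growth rate are tested by permuting covariate labels
at the tumour level (a series never splits), refitting the chosen law per
group, and comparing |r̂_A − r̂_B| with its permutation distribution.
The p-value uses the add-one convention p = (1 + #{perm ≥ obs})/(1 + n_perm)
so p = 0 is impossible. Permuted refits reuse the pooled MLE as a warm
start with a reduced number of cold starts. Default n_perm = 999.

## Synthetic cohorts

`simulate_cohort` emulates the field design; defaults are the stated
world of the motivating study where it gives numbers, and one-time
realistic choices where it does not:

| setting | default | basis |
|---|---|---|
| hosts/tumours | 62 | field cohort size |
| captures per tumour | geometric, mean 87/62 ≈ 1.4 | field measurement:host ratio |
| capture interval | 90 ± 15 days (truncated normal) | quarterly trapping; jitter is a package choice |
| group parameters | diploid: logistic r=0.016, K=364; tetraploid: r=0.026, K=172 (weights 32:10) | published point estimates used as generator settings |
| onset offsets | uniform on [−400, 0] days before first capture | package choice, configurable |
| noise variance ε | 0.04 (σ=0.2, ±20% volume) | package choice: stresses but does not break recovery |
| detection floor | 0.125 cm³ | minimum visible volume |
| mortality | censor at 0.8·K (hard threshold; c=1 disables) | "hosts die as tumours approach maximum volume"; a hazard model is out of scope |
| unknown labels | ploidy unknown w.p. 45/87; location dermal/mucosal/unknown 31/44/12 | field label frequencies |

Ground truth (θ per group, every anchor time re-expressed on each series'
own clock, scheduled/retained/censored/below-floor counts) is stored
alongside. What a green recovery test establishes: the fitters recover
parameters of data whose error model matches the likelihood exactly. What
it does not: robustness to real-data features the generator omits —
heteroscedastic calliper error, within-host tumour interactions, informative
(size-dependent) trapping, growth-rate heterogeneity between tumours of one
group.

## Numerical notes

* Closed forms are used everywhere; invalid times (Mendelsohn finite-time
  blow-up/extinction, cube-root sign changes in von Bertalanffy) return
  NaN in vectorised paths and raise a domain error with the boundary time
  in scalar ones.
* The Gompertz decay clock starts at the anchor t₀ — the only reading
  consistent with its closed form V₀·exp(r/ρ(1 − exp(−ρ(t − t₀)))).
* Optimisation is on log parameters for scale-freeness; reported values
  are natural scale, clipped back to bounds after the exp/log round trip.
* Volume from callipers: rectangular product L×W×D by default (consistent
  with V₀ = 0.5³); the ellipsoid convention π/6·LWD is available via
  `--volume-convention` and echoed into reports, since the field phrasing
  admits both.
* All randomness (starts, chains, permutations, cohorts) flows from
  explicit integer seeds; identical seeds give identical outputs.

## Known limitations

* **AICc on singleton-heavy cohorts over-rewards flexible laws.** With
  mean ~1.4 captures per tumour, ε̂ is estimated on all n measurements but
  only n − m residual degrees of freedom are informative; a competitor
  law's chance improvement in the informative residuals is amplified by
  ~n/(n−m) in log-likelihood, so the ~2-unit AICc penalty for one extra
  parameter is frequently overcome. On synthetic cohorts simulated from
  the exponential law, exponential beats logistic pairwise in ~80% of
  replicates, but some two-parameter law (usually Mendelsohn with b near
  1) wins the five-way comparison about half the time. Model-recovery
  results on such designs should be read with this in mind; the published
  analysis of the real data evidently had enough multi-point series for
  the logistic law to separate cleanly.
* The study's own text is internally inconsistent about which law won the
  mucosal vs dermal splits (its table marks logistic best for mucosal and
  exponential for dermal; its narrative says the reverse, and reports a
  finite K for dermal but not mucosal). The package takes no side: it
  reports whatever the supplied data imply.
* When the best-supported law lacks a carrying capacity (exponential),
  K is simply absent from interval reports (`n/a` situation); there is no
  attempt to extrapolate a final size.
* The hierarchical/empirical-Bayes extension (a population distribution on
  onset times) is deliberately out of scope.
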