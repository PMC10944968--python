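# specdcm

Behavior-conditioned effective connectivity for working-memory experiments:
a tested, reusable implementation of the full analysis chain that links
continuous-report behaviour to directed cortical network dynamics —

1. **Trial classification.** Reports in a delayed continuous-report task are
   modelled as a three-component circular mixture

   p(θ̂) = (1 − β − γ) φ_κ(θ̂ − θ) + γ/2π + (β/m) Σᵢ φ_κ(θ̂ − θᵢ*),

   where θ is the target location, θᵢ* the non-target locations, γ the
   guess probability, β the swap probability and φ_κ a zero-mean Von Mises
   density. Maximum-likelihood fits (EM with multiple restarts) yield
   per-report posterior responsibilities, and trials are labelled *high
   accuracy* (target responsibility > 0.9 in all three reports), *swap*
   (pooled non-target responsibility > 0.7 in at least one report) or
   *low accuracy* (the rest).

2. **Spectral DCM with a conductance-based microcircuit.** Each of 7
   cortical sources (bilateral early visual cortex, intraparietal sulcus,
   middle frontal gyrus, and midline superior frontal gyrus) is a canonical
   microcircuit of four Morris-Lecar-type populations,
   C V̇ = Σₖ gₖ(Vₖ − V) + u, with AMPA- and GABA-A-like conductances driven
   by presynaptic firing rates. Feedforward connections target spiny
   stellate cells, feedback connections target inhibitory interneurons and
   superficial pyramidal cells, lateral (interhemispheric) connections
   carry both; condition-specific modulations (matrix B) scale edges by
   exp(b). The model predicts the 2–100 Hz cross-spectral density (CSD)
   analytically from its linearization and is fitted to multitaper CSD
   estimates by variational free-energy optimization under the Laplace
   approximation, over log-scaling parameters around default priors.

3. **Group inference.** Subject-level posteriors enter a parametric
   empirical Bayes (PEB) model θ⁽¹⁾ = X θ⁽²⁾ + ε⁽²⁾ with an intercept and a
   condition contrast; per-connection evidence comes from Bayesian model
   reduction (Pp = σ(ΔF)), and effect size from leave-one-out
   cross-validated prediction of the group covariate.

Every stage ships with a synthetic-data generator with known ground truth
(mixture-distributed reports under the task's location constraints;
multi-subject stochastic realizations of the network model), so the whole
pipeline is testable end-to-end without any external recordings. Source
selection by time-frequency ANOVA (collapsed F argmax per ROI) is included
for precomputed or synthetic source-power maps; sensor-level preprocessing,
head modelling and beamforming are out of scope.

## Worked example

```python
import numpy as np
from specdcm import (BehaviorSimSpec, simulate_behavior, fit_mixture,
                     responsibilities, classify_trials, behavior_summary)

spec = BehaviorSimSpec(n_trials=500, kappa=8.0, gamma=0.10, beta=0.15, seed=7)
reports = simulate_behavior(spec)           # 3 items/trial, 15 deg min gap
fit = fit_mixture(reports, random_state=0)
print(f"kappa = {fit.kappa_:.2f}  sigma = {np.degrees(fit.sigma_):.1f} deg")
print(f"gamma = {fit.gamma_:.3f}  beta = {fit.beta_:.3f}")
labels = classify_trials(responsibilities(reports, fit))
print(behavior_summary(reports, labels).to_string(index=False))
```

prints

```
kappa = 8.16  sigma = 20.7 deg
gamma = 0.107  beta = 0.156
        label  n_trials  proportion  mean_abs_error_deg
high_accuracy        74       0.148           11.929303
 low_accuracy       312       0.624           29.275308
         swap       114       0.228           52.807812
```

— the generating parameters (γ = 0.10, β = 0.15, κ = 8) are recovered, and
the label-wise mean absolute errors are ordered as the labels intend:
high-accuracy trials ≈ 12°, swap trials ≈ 53° (a swap report is centred on
a non-target, so its error to the target is large).

On the network side:

```python
from specdcm import NetworkModel, build_chain_network, SpectralDCM

arch = build_chain_network(3)               # reduced 3-node hierarchy
truth = {arch.edges[0]: 0.5}                # planted delay modulation
cs_base = NetworkModel(arch).predicted_csd()
cs_delay = NetworkModel(arch, b=truth).predicted_csd()
dcm = SpectralDCM(arch).fit(cs_base, cs_delay)
print(dcm.posterior_["b:n1->n2:feedforward"])   # (mean, sd) near (0.5, ...)
```

The command line mirrors the library: `specdcm simulate-behavior`,
`fit-behavior`, `simulate-spectra`, `estimate-csd`, `invert`, `peb`,
`select-sources`, and `run-all` for a configuration-driven end-to-end run
with a content-hashed manifest (identical configuration + seed ⇒ identical
artifacts).

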