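# Methods

## Behavioral mixture model

Reports of remembered angular locations are modelled per subject as draws
from a three-component mixture: a Von Mises centred on the target, a Von
Mises centred on one of the m non-targets (chosen uniformly, sharing the
same concentration — the swap component is pooled), and a circular uniform
guess. Internally dispersion is parameterized by the concentration κ; the
circular SD σ = √(−2 ln R̄(κ)) with R̄ = I₁/I₀ is derived from it, and
configurations may specify either (the mapping is inverted numerically by
bisection). Densities use exponentially scaled Bessel functions so large κ
does not overflow.

Fitting is expectation-maximisation: responsibilities over the 2 + m
components in the E-step; closed-form weight updates and a weighted
mean-resultant-length update for κ (inverted numerically) in the M-step;
5 restarts from dispersed starting points by default, best log-likelihood
kept. Degenerate data (e.g. all reports identical) drive κ to its cap and
are reported through a `boundary_` flag rather than an exception. Unit
tests check EM against a coarse grid-search maximum-likelihood oracle
built on scipy's Von Mises density.

Trial labels follow fixed responsibility thresholds: high accuracy when
p(target) > 0.9 in all three reports of a trial, swap when the pooled
p(non-target) > 0.7 in at least one report, low accuracy otherwise. The
two gates are mutually exclusive by arithmetic (0.9 + 0.7 > 1 within a
report; the all-report rule handles the rest), so the rule order is fixed
only for determinism. Angles are wrapped to [−π, π) everywhere; summary
errors are reported in degrees.

The behavioral generator samples item locations on an isoeccentric
hemifield arc by rejection: pairwise separation ≥ 15° of polar angle and
≥ 10° clearance from the vertical meridian by default, with a retry cap.
These defaults mirror the task constraints of the study design the
analysis targets; the generator stores the true generating component of
every report so recovery and classification tests have exact ground truth.

## Conductance-based network model

Each source is a canonical microcircuit of four populations — spiny
stellate (ss), superficial pyramidal (sp), inhibitory interneurons (ii),
deep pyramidal (dp). Population state is (V, g_E, g_I): membrane potential
(mV) and excitatory/inhibitory synaptic conductances (normalised to the
leak conductance). Dynamics are Morris-Lecar-like:

    C dV/dt  = g_L (V_L − V) + g_E (V_E − V) + g_I (V_I − V) + u
    dg_k/dt  = κ_k (target_k(rates) − g_k)

with conductance targets linear in presynaptic firing rates, a logistic
rate function of membrane potential, and innovations u entering the ss
population. Intrinsic wiring: ss↔sp excitatory, sp→dp, all three
excitatory populations reciprocally coupled with ii (the reciprocal set is
configurable), and inhibitory self-connections on every population
(synaptic gain). Extrinsic rules: feedforward sp→ss, feedback dp→{ii, sp},
lateral both patterns mixed equally (the mix is a parameter).

Default constants (time in seconds, potentials in mV): C = 0.010
(0.005 for ii) giving a 10 ms membrane constant at g_L = 1; V_L = −70,
V_E = +60, V_I = −90; κ_E = 250 s⁻¹ (≈ 4 ms, AMPA-like), κ_I = 62.5 s⁻¹
(≈ 16 ms, GABA-A-like); rate sigmoid threshold −54 mV, slope 6 mV; tonic
background excitatory drive 0.05 per population. Extrinsic base weights
0.10 / 0.08 / 0.08 (feedforward / feedback / lateral). These are a
documented reference set chosen so that the default 7-node network is
stable (spectral abscissa ≈ −22 s⁻¹) and spectrally active across the
2–100 Hz band with a low-frequency (≈ 13 Hz) resonance; they claim no
numerical equality with any other implementation. All connectivity
estimation happens in log-scaling space around these defaults, so
positivity of effective coupling is automatic and b = 0 is an exact
identity.

The default 7-node architecture ranks EVC(1) < IPS(2) < SFG(3) < MFG(4);
within each hemisphere every lower-rank node projects feedforward to every
higher-rank node, with the midline SFG participating in both hemispheric
chains — 12 feedforward edges, their 12 feedback reverses, and 6 lateral
edges between the three homologous pairs, all condition-modulable. The
edge list is derived from the stated counts and typing rules; since the
ordering of the two frontal regions is the one genuinely open choice, the
alternative SFG-top hierarchy ships as a named preset, and arbitrary
architectures load from JSON.

**Spectra.** The fixed point solves rhs = 0 by damped Newton with an
analytic Jacobian (validated against central finite differences) and a
residual norm that rescales the fast voltage rows by 1/C so the line
search is not dominated by them. The analytic CSD propagates parameterized
innovation spectra (power-law amp·f^(−exponent) plus a white floor,
clamped below 1 Hz) through the transfer function of the linearization and
adds white observation noise:

    S(f) = M(f) diag(G_u(f)) M(f)* + S_noise,   M(f) = C_out (2πif·I − J)⁻¹ B_in

with innovations entering ss voltage equations and the observed signal the
sp potential (one-sided PSD convention throughout: unit-variance white
noise at rate fs has PSD 2/fs). Unstable linearizations raise rather than
return spectra. Simulation uses Heun integration at the sampling step with
spectrally shaped innovations (frequency-domain shaping of white noise,
zero-order hold within a step) and discards a 2 s transient; the
multitaper estimate of a 300 s realization agrees with the analytic CSD
within ~10% at spectral peaks (recomputed by the acceptance suite), which
is the module's core oracle.

## Cross-spectral estimation

Multitaper CSD with DPSS windows: half-bandwidth 2 Hz by default (1.5 Hz
in the long-simulation oracle, where epochs are 2 s), K = max(1, ⌊2NW⌋ − 1)
tapers, per-epoch demeaning (optional linear detrend), averaging over
epochs and tapers, linear interpolation onto the 2–100 Hz / 1 Hz analysis
grid, and explicit re-Hermitization after interpolation. Epochs shorter
than 1/f_min are rejected with the minimum length in the message. The
three canonical 800 ms task windows (baseline −900..−100 ms, early delay
400..1200 ms, late delay 1200..2000 ms) keep 100 ms clearance from
stimulus (0–200 ms) and report (≥ 2200 ms) intervals; window slicing is
bookkeeping over full epochs.

## Inversion (variational Laplace)

One inversion fits a (baseline, delay) CSD pair jointly: the estimated
parameter vector covers extrinsic log-scalings (acting in both windows),
B modulations (delay window only), per-node intrinsic-gain log-scalings,
innovation amplitude and exponent, observation gain and observation-noise
scalings; prior variances per class (defaults 1/16 for extrinsic and B,
1/64 intrinsic, 1/8 innovation amplitude and observation noise, 1/32
exponent and gain) with zero prior means; variance-0 classes are excluded
from estimation. The data vector stacks real upper-triangle and imaginary
strict-upper-triangle entries of both windows, normalised by mean diagonal
power; the likelihood is Gaussian with a single log-precision
hyperparameter under a weak Gaussian hyperprior (mean 4, variance 16) —
the classical variational-Laplace treatment, an approximation documented
as such (cross-spectral sampling noise is in truth heteroscedastic and
correlated).

Optimization is Fisher scoring on the Laplace free energy with Levenberg
damping and revert-on-decrease: after each re-linearization the free
energy is recomputed, and if it fell the parameters revert to the best
state while damping quadruples, so the recorded trace of accepted free
energies is non-decreasing by construction. The noise log-precision is
updated by Newton steps inside each iteration. Convergence: relative
improvement < 1e−2 on 3 consecutive accepted steps, max 128 iterations
(all in the estimator's constructor). Prediction derivatives are central
finite differences (step 0.01 log units) with one-sided fallback when a
perturbed parameter destabilizes the network. On linear problems the
optimizer reduces to exact conjugate Bayesian linear regression (tested
against the closed form); fit quality is summarized by the Pearson
correlation of cross-spectral moduli and R² on the same vectors.

Known limitation: with the noise precision plugged in at its point
estimate, posterior SDs of a few tightly constrained nuisance parameters
(observation noise, innovation exponent) are mildly overconfident — in the
matched-noise self-consistency test ~85% of parameters fall within 2
posterior SDs of truth rather than the nominal ~95%. Sign recovery of
planted modulations, the quantity group inference consumes, is unaffected.

## Hierarchical group model (PEB)

Second level: first-level posterior means m_i with covariances V_i follow
m_i = (x_i ⊗ I) θ⁽²⁾ + ε_i, ε_i ~ N(0, V_i + Σ_b), with X an intercept
plus contrast regressors and Σ_b = exp(γ)·(1/16)·I a single between-subject
variance scale estimated by maximising the exact marginal likelihood
(closed-form Gaussian; bounded scalar search over γ with a weak N(0, 4)
prior). Given γ, the posterior over θ⁽²⁾ is the conjugate precision-weighted
GLS solution with a N(0, 1) prior per second-level parameter — subjects
with larger first-level uncertainty contribute less by construction.
Pairwise condition contrasts are run as separate models with ±0.5 contrast
coding.

Per-connection evidence uses Bayesian model reduction: the prior variance
of one second-level element is shrunk to 1e−8 and the log-evidence change
is computed in closed form (validated against direct conjugate evidence);
Pp = 1/(1 + exp(ΔF)). Leave-one-out prediction refits the model without
one subject and projects that subject's common-effect-corrected parameters
onto the contrast effect by precision-weighted least squares (posterior-
mean mapping only — a documented simplification); predictive accuracy is
the Pearson correlation between true and predicted covariates with its
classical two-sided p, thresholded at 0.05 uncorrected with no further
correction, mirroring the analysis stance it implements.

Known limitation, measured rather than assumed: because each left-out
prediction shares n−1 of n training subjects with every other fold, the
classical p-value's independence assumption fails and the LOO test is
anti-conservative — the null standard deviation of r is ≈ 0.28–0.30
versus the nominal ≈ 0.23 at n = 20, and null rejection rates at the 0.05
threshold run well above nominal (the acceptance suite recomputes this
rate; an independent minimal re-implementation of the same scheme shows
the same behaviour, so it is a property of the procedure, not of this
code). The Pp gate is unaffected. Users should treat the LOO p as a
heuristic effect-size screen, not a calibrated test.

## Source selection

Relative-change baseline correction (power − baseline)/baseline with the
trial-averaged baseline; massive univariate one-way fixed-effects ANOVA
with trial type as the factor at every (source, time, frequency) cell,
trial-level observations (the default resolution of the open question on
observation granularity); uncorrected F summed over the full time-frequency
grid; argmax per ROI with ties broken by lowest source index (candidate
lists are sorted, so the rule is deterministic). Lateralized ROIs are
selected per hemisphere by providing separate candidate sets; bilateral
ROIs are a single set. The ANOVA is validated cell-wise against
scipy.stats.f_oneway.

## Pipeline and reproducibility

One run = one output directory: behavioral simulation → mixture fit and
labels → group timecourse simulation → multitaper CSDs → per-subject,
per-condition inversions → PEB contrast with LOO → effect report, each
artifact content-hashed into a manifest (HDF5 files are hashed by walking
datasets, with timestamp tracking disabled, so reruns are byte-comparable)
along with the seed and a hash of the analysis configuration (output paths
excluded). All randomness derives from one root seed through named
SHA-256 substreams (behavior, subject, noise per subject/condition), so
identical configurations reproduce identical artifacts bit for bit.

## What the generators do and do not emulate

The behavioral generator reproduces the mixture structure, the task's
location-sampling constraints, and three reports per trial; it does not
model sequential report dependencies, response biases toward particular
locations, color similarity of memoranda, or lapses correlated across
reports. The group generator produces source-level signals with the exact
statistical structure the spectral model assumes (linear-regime
conductance dynamics, power-law-plus-floor innovations, white observation
noise, log-normal between-subject connectivity variation) — passing
recovery tests therefore demonstrates internal consistency of the
estimation chain, not robustness to the mismatches of real MEG source
estimates (beamformer leakage and correlated noise between sources,
non-stationarity across the delay period, 1/f deviations, trial-count
imbalance between conditions beyond what precision weighting absorbs).
Sensor-level preprocessing, head modelling and source reconstruction are
out of scope by design; inputs are already source-level.

## Problem sizes

Default test and acceptance scales: 2000 trials per mixture-recovery cell
(27 cells), 300 s at 1 kHz for the spectral oracle, 64 × 0.8 s epochs per
window for inversion recovery on the 3-node chain (10 seeds in the
acceptance suite), 20 subjects for group-level fixtures, 100 replicates
for selection and calibration rates, and a 2-subject / 10-epoch pipeline
fixture for determinism — sizes at which every recovery property is
comfortably inside its tolerance while the whole suite runs on one CPU in
minutes.
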