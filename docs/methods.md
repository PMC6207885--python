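# Methods

## The generative model

Each cortical source is a four-population conductance-based neural mass:
layer IV spiny stellate cells (SS), superficial pyramidal cells (SP),
inhibitory interneurons (II) and deep pyramidal cells (DP).  A population
carries four states — membrane potential `V` and three ligand-gated
conductances `g_AMPA`, `g_GABAA`, `g_NMDA` — giving 16 states per source
and 64 coupled ODEs for the default four-source network:

    C V' = g_L (V_L - V) + g_AMPA (E_Na - V) + g_GABAA (E_Cl - V)
           + g_NMDA m(V) (E_Ca - V) + I_bg
    g_r' = kappa_r ( sum_q W_r[p,q] F(V_q)  - g_r )

`F` is a logistic firing sigmoid with threshold −40 mV and slope
`sqrt(variance)`; `m(V) = alpha / (1 + beta exp(-gamma V))` is the
voltage-dependent magnesium unblocking of NMDA channels (defaults
alpha = 1.5, beta = 0.33, gamma = 0.06 mV⁻¹).  Reversal potentials are
fixed at +60 mV (sodium / AMPA), +10 mV (calcium / NMDA), −70 mV
(chloride / GABA_A) and −70 mV for the potassium leak.  Channel time
constants have prior means 12 ms (AMPA), 8 ms (GABA_A) and 100 ms
(NMDA); their inverses are the rate constants `kappa_r`.

Every free neuronal parameter is a log-scale factor on a fixed prior
mean (`value = prior * exp(lambda)`, `lambda ~ N(0, v)`), which keeps
positivity and makes Gaussian posteriors natural.  The default network
has exactly 41 free neuronal parameters: 12 rate constants (3 receptors
× 4 sources), 16 intrinsic gains (AMPA, GABA_A, NMDA-to-excitatory and
NMDA-to-inhibitory per source), 4 extrinsic forward/backward log-gains,
the shared firing variance and background current, the three magnesium
block parameters, and 4 intra-source delays.  Receptor-wise this
partitions 15 NMDA / 12 AMPA / 8 GABA_A / 6 other.  Interhemispheric
SP→SP couplings exist but are fixed at their prior value and carry no
free parameter, which is what keeps the count at 41.

### Operating point and intrinsic wiring

The intrinsic weights are not free-hand numbers: the AMPA and NMDA
templates are chosen first (stellates drive superficial pyramidals;
superficial pyramidals drive interneurons and deep pyramidals; the
interneurons' excitatory drive is deliberately NMDA-dominated), and the
GABA_A weights are then *solved analytically* so that designed stationary
potentials — (−52, −46, −40, −46) mV for (SS, SP, II, DP) — satisfy the
current balance of an isolated source at prior means.  This places every
population on an informative part of its sigmoid: the pyramidal cells on
the rising flank (so tonic NMDA current controls their gain) and the
interneurons near threshold (so their output tracks pyramidal drive).
The design gives the circuit the property the clinical phenomenology
requires: reducing NMDA signalling onto excitatory cells lowers pyramidal
tone, starves the interneurons of their slow NMDA drive, disinhibits the
fast AMPA/GABA_A loop, and thereby *raises* scalp beta-gamma power while
*lowering* interneuron beta output and moving the system closer to
instability.

### Delays and linearization

The observed CSD comes from linearizing the network about its fixed
point (damped Newton on the stationarity condition, residual ≤ 1e−8).
Synaptic transmission is delayed — one free intra-source delay per
source (prior 3 ms) and a fixed 8 ms inter-source delay — and enters by
first-order compensation, `J_d = (I + D ∘ J)^{-1} J`, where `D` holds
the delay of every voltage-to-conductance coupling.  The transfer
function `H(f) = Out (2πif I − J_d)^{-1} B` is evaluated through the
eigen-decomposition of `J_d`, which yields the stability check (all
eigenvalue real parts < 0) for free.  The stochastic simulator
integrates the *same* delay-compensated vector field (`x' = M f(x)` with
`M = (I + D ∘ J(x*))^{-1}`) with Heun steps at 2 kHz, so the analytic
spectrum and a long simulation agree by construction up to integration
error, finite-sample Welch noise and the (small-amplitude) nonlinearity.

### Observation model

Innovations drive the spiny stellate populations with a power-law
spectrum `G_u(f) = u_amp² (f/32 Hz)^{-u_exp}`; mode-level and spatially
common observation noise have the same form.  The 32 Hz pivot makes the
exponent tilt power about mid-band instead of rescaling everything, so
"EEG slowing" (a larger exponent) raises delta without touching the
beta-gamma band.  The default amplitude (u_amp = 0.001) keeps the
stochastic model in its small-fluctuation regime where the linearized
CSD is accurate; absolute units are arbitrary.  The five observation
parameters are free in every inversion but are not part of the 41
neuronal parameters.

The lead field is schematic: Gaussian fall-off from each source's scalp
projection over the 2-D 10-20 electrode layout, unit-norm columns (a
seeded random gain is also available).  Population contributions to the
source output are SP 0.6, DP 0.3, SS 0.1 and II 0.0 — interneurons are
closed-field and invisible to EEG.

## Inversion

Subject data are the real parts of the upper-triangular CSD entries
plus the imaginary parts of the strict upper triangle, concatenated over
frequencies.  A finite-epoch CSD estimate has entry-wise sampling SD
proportional to `sqrt(S_ii S_jj / K)`, so each entry is weighted by
`1/sqrt(S_ii S_jj)` of the observed diagonal before fitting; with that
weighting a *single* noise-precision hyperparameter is well specified
across the whole band and is updated by expectation-maximization inside
the ascent.  The posterior is Gaussian (fixed-form variational Laplace):
Gauss–Newton ascent on the free energy with Levenberg–Marquardt
regularization, finite-difference sensitivities evaluated as one batched
call (forward differences by default for cohort work, central optional),
steps that destabilize the model rejected outright, and termination when
the accepted free-energy gain falls below tolerance.  On a linear
forward model with fixed noise precision the free energy equals the
analytic log evidence at the optimum, which the tests verify to 1e−6.

Group pipelines invert the 2–48 Hz band jointly.  This matters: the
100 ms NMDA kinetics express below ~6 Hz, and fitting the beta-gamma
band alone leaves NMDA-weight deficits degenerate with AMPA-weight
changes.  Including the low frequencies is what makes the receptor
attribution identifiable at the first level.

Empirical prior calibration mirrors clinical practice: three control
subjects chosen at random are inverted under the default priors and the
prior mean is re-centred on their average posterior before every subject
is (re-)inverted.

## Group inference

The second level is a Gaussian hierarchy over subject posteriors:
`theta_i ~ N(X_i beta, Sigma_i + Q)` with the nested design (mean;
encephalopathy indicator covering both patient groups; NMDAR-encephalitis
indicator), diagonal between-subject covariance `Q` (a shared scale
optimized on the exact evidence), and `beta ~ N(0, 1/16 I)` — the
conventional second-level shrinkage prior.  Everything is jointly
Gaussian, so the `beta` posterior and the model evidence are exact.  One
empirical-Bayes refinement round re-inverts each subject under the
second-level conditional prior (`X_i beta`), the standard EM treatment
of the hierarchy, which consolidates weak but consistent group effects
without biasing null cohorts (verified by the type-I checks).

Bayesian model reduction switches individual (covariate, parameter)
effects off by shrinking their prior variance to ~0; reduced evidence is
analytic from the full posterior.  A greedy prune with an exhaustive
sweep over the last ≤ 8 surviving effects explores the model space
(2^82 full enumeration being infeasible), and per-effect probabilities
come from Bayesian model averaging over every model visited.

CVA is the classical complement: canonical correlations between a
receptor-specific subset of posterior means and the group contrast via
SVD whitening, with Bartlett's chi-square approximation (a permutation
check is provided).  The classifier projects subjects on the first
canonical vector, thresholds at the midpoint of the group means and can
regress an occipital alpha-power covariate (mean 8–12 Hz power of O1/O2)
out of the scores first.

## The synthetic cohort

No patient EEG is distributed, so a generator defines the study
conditions: 29 NMDAR-antibody encephalitis, 18 other encephalopathy and
18 neurological control subjects.  Subject parameters are group effect
plus N(0, 0.03²) between-subject variability on the neuronal
log-parameters (0.06 on observation parameters).  Group effects
(calibrated once, with `scripts/calibrate_effects.py` reporting the
outcome):

- **Encephalitis**: −1.0 on the NMDA rate constants of the right
  parietal and both prefrontal sources and on the intrinsic
  NMDA-to-excitatory weights of the right parietal and left prefrontal
  sources (≈63% loss of function, within the range reported for
  antibody-mediated receptor internalization), a 0.4 share of the
  encephalopathy effect (these patients are encephalopathic too — the
  nested design requires it, and without it the NMDAR-specific contrast
  would pick up spurious non-NMDA differences), plus a broadband
  increase of endogenous drive (+0.15 log units) reflecting cortical
  hyperexcitability.
- **Encephalopathy**: mild shifts across all three receptor classes
  (slowed kinetics, slightly raised AMPA and lowered GABA_A gains) and a
  markedly steeper innovations spectrum (+0.55 on the log-exponent) —
  classical diffuse EEG slowing.

Fast mode samples a complex-Wishart finite-epoch estimate (144 epochs,
matching ~12 min of clean 5-s segments) around each subject's analytic
CSD, with data-driven spatial modes from the subject's own channel-space
CSD.  Time-series mode integrates the stochastic model and runs the full
spectral path (filtering, epoching, artifact screening, SVD modes,
per-epoch VAR spectra).  An optional occipital 10 Hz confound adds a
narrowband component to O1/O2 for a fraction of encephalitis subjects.

### What the generator does and does not emulate

It reproduces the second-order statistics the analysis consumes — group
differences in band power with the clinically observed directions
(encephalitis > control at 28–40 Hz; encephalopathy highest at 2–4 Hz),
finite-sample estimation noise, subject-specific spatial modes, and the
receptor-specific parameter shifts.  It does not attempt realistic
artifacts beyond simple amplitude outliers, eyes-open/closed state
changes, non-stationarity, volume-conduction anatomy, or
large-amplitude nonlinear dynamics (the drive keeps the model in its
linear neighbourhood).  Passing tests therefore demonstrate internal
consistency of the assay under its own assumptions, not performance on
clinical recordings.

## Numerical choices

- Fixed-point solver: short forward relaxation into the Newton basin,
  then batched Newton; warm starts reuse the previous center during
  inversion.  Tolerance 1e−8 on the capacitance-scaled residual.
- Finite differences: step 1e−4 on the log scale; forward scheme for
  cohort work (the gradient bias is negligible against its 2× cost
  advantage), central elsewhere.
- Unstable parameter draws in the generator are rejected and resampled
  (counted); unstable candidate steps in the inversion are rejected as
  infinitely poor fits rather than clamped.
- SVD sign convention: each spatial mode's largest-magnitude element is
  forced positive.
- Problem sizes in the test-suite experiments are scaled-down versions
  of the full study (8/6/6 cohorts for the end-to-end selectivity
  replicates, 400–600 s simulations for the generative consistency
  check); the full 29/18/18 cohort is used wherever no inversion is
  required.

## Known limitations

- The first-order delay compensation is shared between the analytic and
  stochastic paths by construction; it is an approximation to true
  delay-differential dynamics that degrades above ~40 Hz for the 8 ms
  inter-source delay.
- Single-subject receptor attribution is weakly identified — posterior
  probability mass spreads across correlated NMDA parameters (e.g. an
  intrinsic NMDA weight and the magnesium-block gain); the hierarchical
  level is what resolves the attribution, mirroring the motivation for
  group-level empirical Bayes.
- The exhaustive BMR sweep covers only the effects surviving the greedy
  prune; probabilities for strongly correlated surviving effects are
  conservative.
- The synthetic lead field ignores anatomy; only the mixing structure is
  meaningful.
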