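# Methods

## The model

`gammadcm` implements a computational assay of cortical excitation–
inhibition balance from single-virtual-sensor MEG spectra.  The
generative model is a four-population canonical microcircuit (CMC) of
visual cortex: layer-4 spiny stellate cells (SS), layer-2/3 superficial
pyramidal cells (SP), inhibitory interneurons (II) and layer-5/6 deep
pyramidal cells (DP).  Each population p carries two states, a membrane
depolarization v_p (mV) and a synaptic current proxy i_p, evolving under
a critically damped second-order synaptic kernel

    dv_p/dt = i_p
    di_p/dt = kappa_p (u_p - 2 i_p) - kappa_p^2 v_p,

where kappa_p is the population's synaptic rate constant (1/s) and u_p
sums the signed, sigmoid-transformed presynaptic voltages over the fixed
edge table, u_p = sum_k sign_k G_k f(v_source(k)).  Exogenous drive
(endogenous afferent input) enters SS only.  The firing transform is a
logistic sigmoid with its resting value subtracted, f(v) =
1/(1+exp(-rho v)) - 1/2 with slope rho = 2/3 per mV, so the origin is an
exact fixed point at zero drive and the linearization point is
well-defined.

Twelve signed intrinsic couplings connect the populations.  Four edge
roles follow the standard nomenclature of this circuit family — G4 =
II→II self-inhibition, G6 = DP→II excitation, G7 = SP→SP
self-inhibition, G11 = II→SP inhibition — and the remainder complete a
conventional laminar layout (granular input to both pyramidal layers and
to the interneurons; interneuron inhibition of every population;
inhibitory self-gain control on each population).  Every coupling is
parameterized as G_k = Gbar_k exp(gamma_k): the free parameters gamma_k
are dimensionless log-scalings with prior mean 0, and the
excitatory/inhibitory sign lives in the edge table, never in gamma.

## Spectral forward model

The predicted sensor spectrum is obtained by linearization: fixed point
→ Jacobian J → transfer function H_p(f) = [ (i 2 pi f I − J)^(−1) B ]_p
with B routing the drive into the SS current equation → input spectrum
g_u(f) = alpha (1 + beta / f), a mixture of white and scale-free
fluctuations → weighted-contribution observation with channel noise:

    S(f) = gain * | sum_p w_p H_p(f) |^2 * g_u(f) + n_w + n_f / f.

The default observation weights are SP-dominant (0.8 SP, 0.2 DP),
reflecting the pyramidal-current origin of the MEG signal.  The fitting
grid is 4–90 Hz at 0.5 Hz spacing (173 points); we fit log power, which
makes the residual model multiplicative in power and scale-free.

### Calibration of the prior means

The exact priors of the original modelling software are not published,
so the prior means here were tuned once (`scripts/calibrate_priors.py`)
and then frozen.  Two analytic facts guided the tuning.  For two
critically damped kernels in a negative loop, marginal oscillation
occurs at omega = sqrt(kappa_a kappa_b), and requires loop gain
G_a G_b f'(0)^2 = (kappa_a + kappa_b)^2.  The gamma rhythm is therefore
carried by the fast SS↔II loop (G3/G9), placed at ~60% of its critical
gain with kappa = (440, 256, 325, 96) 1/s for (SS, SP, II, DP).  At the
prior means the spectrum peaks at 56 Hz; the operating point is stable
(spectral abscissa −80 s^-1) and remains stable over coupling draws of
the size used by the cohort generator (0 unstable in 400 draws).

Measured sensitivities of the calibrated circuit (peak over gamma_k in
[−0.6, 0.6]): g4 raises peak frequency and lowers amplitude (54.5→59 Hz);
g9 is the strongest frequency control (44.8→66.8 Hz); g11 raises gamma
amplitude and lowers peak frequency (57.2→54.8 Hz, monotone — this
direction is frozen in the test suite); g5/g6/g8/g12 have weak spectral
leverage, which is physiologically sensible for deep-layer edges read
through a superficial-layer-dominated sensor.

## Inversion (variational Laplace)

Free parameters are the 8 reported coupling log-scalings (g4–g9, g11,
g12) plus input, channel-noise and observation-gain log-scalings
(optionally the four rate constants).  Priors are Gaussian with mean 0
and variance 1/16 on couplings and rate constants, 1/8 on the others.
The posterior is Gaussian (Laplace): a Gauss–Newton ascent on the log
joint of log-power residuals and priors, with Levenberg–Marquardt
damping (accepted steps only), a conjugate closed-form update of the
residual precision each outer iteration (Gamma(1, 0.05) hyperprior), and
numerical gradients by central differences (step 1e−4 on the log scale).
Iteration stops when |dF| < 0.01 nats four times in a row, or at 128
iterations.  The reported free energy adds the Gaussian entropy and
prior normalization at the mode, making it usable for comparing free
sets (the generating free set beats a deliberately wrong one in the test
suite).  The optimizer is fully deterministic; the seed argument is
provenance only.

Parameter recovery under the documented conditions (20 spectra, free
couplings ~ N(0, 0.25^2), 20 dB multiplicative observation noise):
rank correlation of recovered vs generating values exceeds 0.8 for both
g4 and g11.

## Gamma features from trials

Virtual-sensor epochs span [−2, +2] s around stimulus onset at ≥600 Hz.
For each center frequency (1–100 Hz in 0.5 Hz steps by default) the
epochs are zero-phase Butterworth bandpass filtered (order 4, ±2 Hz),
the analytic-signal envelope taken, averaged over trials, and expressed
as percent change from the mean prestimulus baseline; 0.25 s edges are
trimmed before any statistic.  Trial averaging before percent change is
the default (capturing the evoked+induced mixture); per-trial
normalization is available.  Peak features are the band maximum
(30–80 Hz) of the window-averaged map: transient 0–0.3 s, sustained
0.3–0.8 s, prestimulus −1.5 to −0.5 s; ties break toward the lower
frequency.  The filter family, order and bandwidth are declared choices;
the narrow bands ring for ~1 s, which the tests account for when
checking envelope flatness.

## Psychophysics

The 2AFC orientation-discrimination task is modelled with a
cumulative-Gaussian observer: P(correct | delta) = lapse/2 + (1−lapse)
Phi(delta / (noise sqrt(2))), lapse fixed at 0.02 (configurable).  The
simulator uses the method of constant stimuli (7 log-spaced deltas).
The threshold is the delta at 75% correct on the fitted curve; the
single free parameter (internal noise) is fitted by maximum likelihood
on a log scale with a deterministic start at the median tested delta.
Estimator bias is below 5% at 10^4 trials.  The oblique condition is
generated with larger internal noise than vertical, reproducing the
oblique effect.

## Group statistics

Pooled and Welch two-sample t-tests (summaries or samples), a 2×2 mixed
ANOVA (two groups × two within-levels; two levels make sphericity
machinery unnecessary), Pearson correlation with the t-based p, and
Bonferroni correction min(1, m p).  The default-prior (JZS) two-sample
Bayes factor uses a Cauchy prior (scale 0.707) on the standardized
effect, evaluated through its normal-by-inverse-gamma mixture with
adaptive quadrature; tests pin it to a dense trapezoid oracle and to an
independent implementation at 3 significant figures.  Best-vs-rest
evidence ratios divide the largest BF by each BF.  Note that for
unequal group sizes the mixed ANOVA's within-factor main effect uses
group-size-weighted means (the behaviour of the backing implementation);
group and interaction effects are unaffected.

## Synthetic cohort generator

The generator emulates the study's structure: 29 controls and 27 SZ
subjects.  Per-subject coupling log-scalings are drawn N(0, 0.2^2) on
the 8 free couplings, with SZ group means shifted down on g4 (−0.25),
g6 (−0.20), g7 (−0.20), g11 (−0.25) and g12 (−0.15) — reduced
superficial-layer inhibition and deep-to-interneuron drive.  Sustained
peak frequency targets are drawn per group from N(58, 4.95^2) and
N(55, 4.94^2) Hz (SE 0.92/0.95 converted to SD via the group sizes).

Each subject's frequency is realized by a synaptic-speed dilation: one
factor c added to every kappa and coupling log-scaling rescales time
exactly, so the model spectrum is a frequency-dilated copy of itself
with stability preserved and the peak proportional to exp(c).  c is
solved per subject by a log-ratio fixed-point iteration against the same
peak measure used downstream.  The measured sustained peak is the
parabolically interpolated argmax of the 2 Hz-smoothed log spectrum in
30–80 Hz — the spectral analogue of peak-picking a window-averaged
envelope spectrum, and markedly less biased than a raw noisy argmax for
broad peaks.  Observed spectra carry multiplicative log-normal noise
(sd 0.1, i.e. ~20 dB SNR).

SANS scores (SZ only, clipped to 0–125, mean 40, sd 18) are a linear
function of the subject's effective g4 plus noise, with the slope set
from the empirical g4 spread so the correlation hits the target
r = −0.7; because the speed factor enters g4, slower (lower-frequency)
subjects also score higher, echoing the frequency–symptom association.
Thresholds per condition are linear in effective g11 (stronger II→SP
inhibition → better performance) with noise calibrated to a target
within-group R^2 of 0.38, vertical base 2.0° (sd 0.6), oblique base 6.0°
(sd 1.5), plus SZ offsets (0.5°/1.5°); thresholds are floored at 0.1°.
The GABA covariate is drawn independent of everything, mirroring the
study's null GABA–gamma correlations.  The SZ subsample size carrying
SANS defaults to all 27, as the original subsample is unreported.

What the generator does not emulate: raw multichannel MEG, beamforming,
artifact structure, head movement, session-to-session variability
(sessions can be emulated by reseeding), and any nonstationarity within
the sustained window.  Passing tests therefore validate the analysis
chain and its calibration, not claims about real recordings.

## Numerical choices

* Integration: fixed-step RK4 with midpoint interpolation of the
  (band-limited) drive path, dt = 0.5 ms; a first-order Euler–Maruyama
  step is available.  At kappa dt ≈ 0.2 the Euler pole mapping shifts
  the gamma resonance by ~3 Hz, which is why RK4 is the default; the
  analytic spectrum then matches the Welch spectrum of a 120 s
  simulation to 6–9% relative L2 over 30–80 Hz.  Trajectories whose
  voltage exceeds 500 mV abort with the offending parameters named.
* Drive synthesis: frequency-domain coloring to the input spectrum, with
  the 1/f term capped below 1 Hz so finite records stay bounded.
* Fixed points at nonzero mean drive use a hybrid Powell root with a
  1e−9 residual acceptance; the zero-drive fixed point is exact.
* Welch comparisons use 2048-sample segments after discarding 1 s of
  transient.
* Problem sizes in the test suite are chosen to exercise each documented
  condition at the stated statistical strength: 1000 replicate cohorts
  for the frequency-difference calibration, three 120 s simulations for
  oracle equivalence, 20 inversions for recovery, 10^4 null simulations
  for type-I calibration, 50 seeds for threshold bias.

## Known limitations

* The edge-role assignment beyond the four named couplings is a
  convention, not a claim about the original layout; it is data
  (serializable in the edge table), not code.
* Whether the original analysis fitted complex cross-spectra, amplitude
  or log power is unknown; log power of a single sensor is fitted here.
* Deep-layer couplings (g5, g8, g12 and partly g6) are weakly
  identifiable from a superficial-dominated sensor; their posteriors
  shrink toward the prior.
* The psychophysical staircase and threshold criterion of the original
  task are unknown; constant stimuli with a 75% criterion are used.
* gamma_11 modulates measured peak frequency by only ~2 Hz over ±0.6,
  so between-subject frequency variance is carried by the synaptic-speed
  factor rather than by g11 alone.
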