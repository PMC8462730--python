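# Methods

## Tuning model

Every simulated neuron is a direction-tuned unit whose noise-free grating
response is a peak-normalized Von Mises lobe on top of a constant
background:

    f(θ) = baseline + A·exp(k(cos(θ − θ_pref) − 1)) + A_anti·exp(k(cos(θ − θ_pref − 180°) − 1))

The lobe is normalized so its peak equals the amplitude `A` for every
concentration `k` (the experimental constraint fixes peak firing rates,
not the Von Mises normalizing constant), giving the closed-form full width
at half maximum FWHM = 2·arccos(1 − ln2/k). The optional anti-preferred
lobe `A_anti` at θ_pref + 180° exists to control direction selectivity
independently of tuning width (below).

**Component cells** respond to the local directions of a plaid's two
constituent gratings: their plaid tuning is the unrenormalized sum of two
lobes centered at the global direction ± half the cross-angle (120°/2 by
default). At low k the summed peak exceeds `A`; this is accepted because
the broad-tuning regime is only used for curve-shape comparisons.
**Pattern cells** respond to global direction: their plaid tuning equals
their grating tuning, optionally broadened by dividing k by
`plaid_k_divisor` (default 4 in the large-population scenarios, emulating
the imperfect cross-angle invariance of real rodent pattern cells).
Cross-orientation suppression — the weakened response to a preferred
stimulus superimposed with another orientation — is modeled
multiplicatively on the above-baseline plaid response
(`plaid_suppression`); for k ≥ 5 this coincides with the peak-response
ratio to better than 1 %.

Trial responses add zero-mean Gaussian noise to the tuning value
(σ = 0.25 response units in the 24-cell scenarios, 2 spikes/s in the
1000-cell scenarios). Gaussian rate noise is the primary model because it
is what the simulations are parameterized with; a Poisson spike-count
option exists (`sample_responses(..., noise="poisson")`). Negative
Gaussian samples are left untruncated by default — the linear readout is
unaffected by a sign-preserving noise model, and truncation would bias
the tuning means — with a `clip_negative` flag for users who want
nonnegative rates.

## Selectivity indices and width calibration

Two standard index families are implemented (`compute_osi_dsi`):

- **ratio**: OSI = (R_pref − R_orth)/(R_pref + R_orth), DSI analogous with
  the anti-preferred response, both on the evoked (above-baseline) tuning.
  Computing them on evoked responses keeps the indices invariant to the
  baseline and makes the usual published ranges attainable (with the
  baseline folded in, an amplitude-8 / baseline-2 cell could never exceed
  OSI = 2/3).
- **vector**: global indices from the normalized first and second Fourier
  moments of the whole evoked tuning curve (1 − circular variance at the
  corresponding harmonic).

`calibrate_k` inverts either definition: the anti-preferred lobe ratio
follows in closed form from the DSI target (for the vector form the two
decouple exactly — the second harmonic is independent of the anti-lobe),
and k is then found by bisection on the OSI target, which is monotone in
k. Unattainable targets raise `CalibrationError` carrying the maximum
achievable index; population sampling clamps per-cell target draws into
the feasible range instead.

The **vector form is the population-calibration default**, a deliberate
design choice. At the target distribution OSI ~ N(0.7, 0.1) the two forms
imply very different tuning widths: the ratio form gives k ≈ 1.9
(FWHM ≈ 100°), the vector form k ≈ 6.1 (FWHM ≈ 55°). Only the sharp
regime is consistent with the rest of the model's documented behavior —
component/pattern codes are distinguishable only for k ≳ 5, rodent
visual-cortex tuning is sharp, and with broad tuning the k/4 plaid
broadening of pattern cells so degrades their informativeness that the
no-suppression pruning control no longer preserves the population's 80/20
class composition. The ratio form remains available and fully supported
for single-cell use.

## Decision neuron

The readout is a logistic classifier over the population response vector,
trained on noisy samples of the two training stimuli (0° = rightward as
positive class, 180° = leftward) by minimizing

    Σ_trials cross-entropy + (λ/2)·‖w‖²     (bias unpenalized, λ = 1 by default)

with L-BFGS on the analytic gradient — full-batch and deterministic, so a
fixed training set yields bit-identical weights. Convergence requires the
gradient's infinity norm to fall below `optimizer_tol` (default 1e-8)
relative to the cost scale; failure raises with diagnostics. The bias is
excluded from the penalty (standard practice). The L2 term doubles as the
homeostatic constraint in the norm analyses: when cross-orientation
suppression shrinks the input vectors for one stimulus class, the
regularized optimum compensates with proportionally larger weights,
approximately equalizing the weighted input across training regimes.

Generalization curves report the fraction of *hard* classifications
(probability > 0.5) over noisy test trials — not mean predicted
probability — with test noise equal to training noise and 500 test trials
per direction by default on the 0°–345°, 15°-step grid. With an
equispaced population and symmetric training set the curves obey two
exact symmetries (up to binomial noise): p(θ) = p(360° − θ) (even about
the 180° midpoint) and p(θ) + p(180° − θ) = 1 (left/right flip swaps the
classes).

## Pruning and pool composition

`prune_by_quantile` zeroes the ⌊q·n⌋ smallest weight magnitudes
(rank-based with a stable sort, so exact ties prune the earlier index
first); this equals quantile thresholding for untied weights, pins the
survivor count to ⌈(1 − q)·n⌉, is idempotent at a fixed quantile and
nested across quantiles. `class_fractions` reports the component/pattern
composition of the surviving decoding pool; the default profile grid is
q = 0 … 0.9 in steps of 0.1 (the analysis needs a non-empty pool, and the
interesting reversal happens by 90 %). Single pruning runs at heavy
quantiles fluctuate beyond the naive binomial band because survival is
determined by correlated learned weights; claims about pool composition
are therefore evaluated on expectations across populations.

## Behavioral pipeline

Trial validity: priming-phase responses must arrive 300–1000 ms after
target onset (faster → "too fast", later or absent → "ignored";
reaction time exactly 300 ms is kept, since the abort rule is RT < 300 ms);
training-phase responses are accepted from 300 ms after onset to 2 s after
offset of the 2 s stimulus. Missing reaction times are "malformed".

The priming curve is accuracy versus the *unsigned* angular distance
between prime and target direction (0°…180° in 10° steps), pooling both
targets — the only reading that yields a 19-point curve with coherent and
incoherent endpoints and a neutral 90° midpoint. Empty bins propagate as
missing, never as zero. The priming magnitude is the mean
|accuracy − neutral accuracy| over the 8 extreme points (4 per side),
using the animal's own 90° bin as neutral; animals below 5 % identity
magnitude are excluded from group analysis (threshold exclusive below).
Note the statistic is an absolute value: on finite data its estimate has
a positive sampling floor even for an unprimed animal, so "no priming"
comparisons should be relative, not against zero.

Group statistics: sessions (not trials) are the bootstrap unit; each
replicate resamples every animal's sessions with replacement
independently, recomputes per-animal curves and magnitudes, and averages
animals with equal weights (missing bins drop out via NaN-aware means).
Confidence intervals are normal (mean ± z·bootstrap SD), reported raw —
they may exceed [0, 1] and are not clipped. The 19 curve-point CIs use the
Bonferroni-adjusted critical value (α/2m, m = 19); scalar magnitude CIs
and the identity-minus-cross difference CI are unadjusted. Group
comparisons use the unpaired two-tailed pooled-variance t-test, with
degenerate (zero-variance) inputs flagged.

## Synthetic cohorts

The generator emulates the priming experiment's design: targets uniform
on {0°, 180°}, prime kind uniform on {grating, plaid}, prime direction
uniform on the 19-direction grid, prime 75 ms / ISI 75 ms / target 750 ms
timing implicit in the 300–1000 ms response window. A correct choice
occurs with probability (1 − lapse)·(base + gain·b(d)) + lapse/2, where
b(d) is a bias profile equal to +1/0/−1 at d = 0/90/180 — by default a
logistic in distance centered at 90° with 25° slope (the identity-priming
curve is approximately sigmoidal), with a linear option for sensitivity
checks. Contaminant trials are injected at configurable rates with
reaction times outside the valid window, and the ground-truth record
carries each animal's exact expected curves, magnitudes and contaminant
counts, enabling exact exclusion accounting and coverage tests of the
bootstrap CIs.

Default study conditions: 11 G-group rats (grating targets) and 10
P-group rats (plaid targets); neutral accuracy 0.75; identity gain 0.15
for everyone; cross gain 0.02 (G) versus 0.15 (P) — producing the
nearly-flat G cross-priming curve and the overlapping P curves; lapse
0.05, too-fast 0.03, ignored 0.05; 10 sessions × 300 trials (per-animal
session trial counts are not constrained by the experimental design, so a
typical high-throughput operant-box session size was chosen). Session
accuracy is stationary by default; `simulate_training_sessions` provides
an exponential learning ramp for exercising the learning-curve metrics.

What the generator does *not* emulate: reaction-time process structure
(RTs only exercise the validity filter), sequential/history effects,
session-to-session drift in the priming phase, and between-animal
heterogeneity beyond independent sampling noise. Passing
parameter-recovery tests therefore demonstrates the correctness of the
estimator and its CIs under the assumed trial model, not robustness to
real rats' nonstationarities.

## Problem sizes and numerics

The scenario recipes use the full study scales (24 cells with 500 train /
500 test samples per condition; 1000 cells with 200 train samples per
class; 50 bootstrap replicates), which run in seconds. Coverage
experiments use scaled cohorts (3 animals, 5 sessions × 150 trials, 50
repeats) — large enough that the bootstrap CI is informative, small
enough to repeat many times. FWHM measurement uses a 720 001-point grid
with bisection refinement; k calibration uses Brent's method to 1e-6.
All randomness flows through seeded `numpy` generators; scenario child
seeds are derived deterministically and kept below 2³¹.

## Known limitations

- The decision neuron is linear-logistic; no nonlinear readouts or
  multiclass decoding.
- Tuning curves are direct functions of direction: no spatial receptive
  fields, spatiotemporal filtering or stimulus rendering.
- The homeostatic account uses L2 regularization as a stand-in for
  synaptic scaling; no mechanistic plasticity model.
- Priming curves are described nonparametrically; no psychometric
  function is fitted.
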