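# Methods

`thermodrift` implements the computational analysis of a whole-body thermal
chamber-preference assay (CPT) and of warm-stimulus calcium imaging in
cultured dorsal-root-ganglion (DRG) sensory neurons, together with
synthetic-data generators that provide ground truth for every stage.  This
note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data can and cannot show.

## 1. Decision model for chamber visits

A visit to a chamber is modelled as a one-choice drift-diffusion process:
an accumulator `x(t)` starts at `z·a` between absorbing bounds `0` and `a`
(boundary separation `a` in evidence units, relative start `z ∈ (0,1)`) and
evolves as `dx = u dt + σ dW` with the within-trial diffusion coefficient
fixed at `σ = 1 evidence·s^-1/2`.  Hitting the upper bound means "leave the
chamber"; the visit duration is the first-passage time (FPT) through that
bound.  Across visits the drift is drawn per visit from `Normal(v, sv²)`:
`sv` is classic inter-trial drift variability, which is what "noise" means
throughout this package.  Because only one choice is observed, the relative
start is fixed at `z = 0.9`, which pushes essentially all probability mass
onto the leave bound; the residual lower-bound mass is a modelled defect,
not a second choice.  Some descriptions place the bounds at `−a` and `+a`;
that is an affine relabelling of the convention used here and `z = 0.9`
denotes the same starting position in both.

σ is not identifiable jointly with (v, sv, a) and is therefore a fixed
convention; all parameter values in this package are on the σ = 1 scale.

### Density, absorption, survival

The upper-bound FPT density is evaluated with the standard pair of series
expansions of the Wiener FPT density (small-time image sum, large-time
eigenfunction sum), switching per evaluation point to whichever series
needs fewer terms at a truncation error of 1e-8.  For `sv > 0` the Gaussian
drift mixture is analytic: the drift enters the density only through
`exp(u·b − u²t/2)` (with `b = (1−z)a` the start-to-bound distance), whose
normal mixture is the closed-form factor

    (1 + sv²t)^{-1/2} · exp[(sv²b² + 2vb − v²t) / (2(1 + sv²t))].

Everything is computed in log space, which keeps boundary separations of
hundreds of evidence units (the realistic-session regime) finite, and makes
the gradient of the log density with respect to `v` and `sv` a two-line
analytic expression — the basis of the gradient-based sampler below.

The eventual upper-absorption probability uses the classical closed form
`(1−e^{−2vza})/(1−e^{−2va})` (stable branches for large |2va|, Taylor
expansion near v = 0; Gauss–Hermite mixing over the drift for sv > 0).

Censored visits (cut short by the session end) contribute the *proper*
survival mass `P(T_upper > t) = 1 − F_upper(t)`, which includes drift draws
that never reach the leave bound (the animal "settles").  This matches the
generative process exactly; the defective alternative `P_upper − F_upper`
differs by the never-leave mass, which is non-negligible once `sv` lets
drift draws go negative.  `F_upper` is computed by composite Simpson
quadrature on 257 log-spaced nodes spanning 14 natural-log units below the
censoring time; at the behaviour scale this is accurate to ~3e-6 relative.

### Simulator

`simulate_fpt` uses Euler–Maruyama (default `dt = 1e-3 s`) with two
accuracy refinements, both validated against the analytic density:

* a Brownian-bridge crossing test per step (crossing probability
  `exp(−2 d_prev d_next / dt)` for each bound), removing the O(√dt)
  first-passage bias of the naive scheme;
* uniform attribution of the crossing time within the crossing step, so
  that returned times are not lattice-valued (at parameter scales where
  passage times are ~100 steps, the lattice alone would dominate a
  histogram comparison).

With these, 16-bin equal-mass total-variation distance between simulated
histograms and the analytic conditional density is below 0.01 at 1e5 paths
across a 3×3×2 grid of (v, sv, z) at a = 1.

## 2. Synthetic behaviour sessions

The generator is the generative twin of the model.  Defaults define the
study conditions and were fixed once:

| parameter | default | rationale |
|---|---|---|
| z | 0.9 | the one-choice fix |
| a | 200 evidence | with σ=1 this puts the start-to-bound distance at 20, giving visits of tens of seconds and ~60–100 visits per 30-min session, matching the assay's phenomenology |
| wildtype neutral (v, sv) | (1.0, 0.30) | ~25 s visits at the preferred 31 °C |
| wildtype test (v, sv) | (1.3, 0.45) | warmer chamber: leave sooner, noisier accumulation |
| mutant test (v, sv) | (1.8, 0.75) | the recovery condition: +0.5 drift, +0.3 variability offsets in the test chamber |
| animal random effects | SD 0.10 on drift; SD 0.10 on the pre-softplus sv scale | modest individual differences |
| session length | 1800 s | 30-min assay |
| frame rate | 20 Hz | camera range of the assay (20–30 Hz) |

Per visit, a drift is drawn from the animal's cell distribution and a
single diffusion path is simulated until the leave bound or the session
end; the final visit is truncated and flagged censored (truncation, not
resampling, so the censoring structure matches real sessions).  Visit
boundaries are snapped to the 1 Hz analysis grid — the resolution of the
downstream position traces — perturbing a drawn FPT by at most 0.5 s.
This makes the track → visits round trip exact and is negligible against
visit durations of 10–30 s.  A lower-bound absorption (possible only for
rare negative drift draws) leaves the animal in place until the session
ends, consistent with the likelihood's survival term.

Keypoint rendering places six animal keypoints at fixed body offsets around
a centroid performing an Ornstein–Uhlenbeck wander inside the occupied
chamber (tunnel transit instantaneous at 1 Hz), plus eight static reference
points (four floor corners, four cage tops).  Prediction dropout and
wall-climbing frames are injected as *exact* fractions of frames so the
quality-control thresholds can be tested at their boundaries (e.g. a
session with exactly 95.0% climbing frames must not be flagged under the
strict `>` rule).

## 3. Trajectory processing

Follows the session-processing chain of the assay: predictions below 0.95
likelihood are censored; sessions with more than 25% missing animal-keypoint
predictions are rejected (strict inequalities, as printed); remaining gaps
are linearly interpolated over the frame index (edges filled from the
nearest valid frame); sessions with more than 95% of frames between the
floor-corner and cage-top levels are rejected as climbing.  The animal's
position is the centroid of the two ears, body centre and tail base, scaled
per frame to the tracked floor corners (cancelling camera drift),
averaged within each second (the downsampling rule is our choice; only
"1 Hz" is prescribed) and truncated to the first 30 minutes.

Visits are maximal runs of chamber occupancy; tunnel samples attach to the
visit they interrupt (leading tunnel samples join the first chamber
entered), the last visit is censored, and a crossing is a completed chamber
change — tunnel entries that return to the same chamber ("probing") do not
count.  Summaries: test-chamber time fraction per 3-minute bin; rolling
mean visit length and crossing counts in 3-minute windows lagged by 1
minute, with windows keyed on visit *start* times (a visit belongs wholly
to the windows containing its start).

## 4. Hierarchical inference

One row per visit; full-factorial treatment-coded fixed effects of
temperature-combination × chamber × genotype (references: wildtype, neutral
chamber, first temperature combination) on both the drift `v` (identity
link) and the drift variability `sv` (softplus link), with per-animal
random intercepts on both linear predictors.  Priors: Normal(0, 2) on
coefficients, HalfNormal(1) on random-effect SDs — the source analysis
reports neither priors nor links, so these are package design decisions,
configurable through `ModelSpec`.  Each of v, sv, a can be a predictor,
floating (one shared value) or fixed; z is fixed (0.9).  A per-cell
("predictor") boundary separation is not supported — the acceptance-relevant
model family fixes `a`, and a fixed `a` lets the expensive drift-independent
series factor of every observation be cached across the whole MCMC run.

The random effects use a *mixed parameterisation* chosen by identification
strength: drift effects are centred (dozens of visits pin each animal's
drift offset, so centring is the well-conditioned form), while the
drift-variability effects are non-centred (`u_sv = τ_sv·ζ`, `ζ ~ N(0,1)`;
per-animal sv offsets are weakly identified and the non-centred form
removes the small-τ funnel).  This choice emerged from observed sampler
pathologies in each pure parameterisation and is the standard remedy.

### Sampler

Gradient-based MCMC, implemented in-package:

1. **Expansion point.**  The joint mode of a centred hierarchy is a
   degenerate spike at τ→0, so the "MAP" is taken empirical-Bayes style:
   L-BFGS over all parameters with the τs frozen, then moment-matching each
   τ to the spread of the fitted effects (twice).  This lands in the
   posterior bulk.
2. **Laplace whitening.**  A finite-difference Hessian of the exact
   gradient at that point; saddle directions are treated by curvature
   magnitude.  Its inverse square root whitens the space.
3. **Pilot window.**  A short HMC run re-estimates per-coordinate scales
   and the centre in whitened space (the Laplace scales of hierarchical
   scale parameters are unreliable).
4. **Main run.**  HMC with dual-averaged step size (target acceptance 0.8)
   and leapfrog lengths jittered in [2, 6]; energy errors above 1000 count
   as divergences.

Defaults are 4 chains × 2000 tuning × 2000 draws (the full reproduction
profile); the scaled test profile is 2 × 500/500.  Runs with more than 1%
divergences or any split-R̂ above 1.01 are flagged (never silently
accepted); a posterior with median sv below 0.02 additionally raises a
near-degeneracy flag.  R̂/ESS come from ArviZ.

### Model comparison and contrasts

Pointwise log-likelihoods per draw feed ArviZ's PSIS-LOO; a model is
unreliable if any Pareto k̂ exceeds 0.7 and unreliable models are excluded
from rankings.  Observations whose log-likelihood is constant across draws
(very short censored visits with survival ≈ 1) have degenerate importance
weights; LOO is exact for them and their k̂ is reported as 0 rather than
the numerically meaningless infinity.

Contrasts are neutral-chamber-corrected and wildtype-subtracted: per
genotype and temperature combination, the draw-wise (test − neutral)
population cell mean minus the same quantity in wildtype, on the natural
scale for both v (linear) and sv (softplus of the cell-mean linear
predictor); medians with central 94% intervals.

## 5. Synthetic calcium recordings

Defaults emulate one field of view (FOV) of a 3-day DRG culture: 300 cells
of which 6% are warm-sensitive responders (the prevalence reported for
3-day cultures), 70% of responders with dynamic-phase onsets; a 1-minute
baseline; three ascending 25-s warm stimuli at 5-minute intervals; optional
capsaicin (TRPV1 gate) and high-KCl (viability gate) epochs; 10 Hz
sampling.  The three plateau temperatures are not printed as numbers in the
source and are free protocol parameters; the defaults (34, 37, 40 °C,
from a 32 °C bath, 8-s linear ramp, exponential relaxation) ascend within
the warm (< 43 °C) range.  Responder transients are
difference-of-exponentials kernels (1 s rise, 8 s decay) with amplitude
scaled by stimulus index (graded-monotonic tuning); raw fluorescence
composes the cell signal, 70% of a shared neuropil trace, multiplicative
bleaching (15% amplitude, 600 s time constant) and Gaussian noise (SD 2 on
a ~100 a.u. baseline).  The returned neuropil matrix is the noise-free
spatial-average contamination regressor, so the 70% subtraction recovers
the clean cell trace up to the shot noise.  Negative composed fluorescence
is clipped at zero with a warning.

## 6. Calcium trace pipeline

* **Normalisation**: `ΔF/F0 = (F − F0)/F0` with two F0 conventions — the
  session convention (mean of the first 10 s, used for heat maps and cell
  ordering) and the per-stimulus convention (mean of the first 10 frames of
  each window `[start − 10 s, end]`).  Cells with `F0 ≤ 0` are flagged
  invalid and excluded.  Optional clipping at the 0.1/99.9 percentiles.
* **Phase split**: the temperature rate is smoothed with a centred 2-s
  moving average; within each stimulus the boundary is the first time after
  the rate peak at which the smoothed rate falls below 10% of the peak.  A
  moving average delays that crossing by exactly `w·(1/2 − frac)` on an
  ideal ramp-plateau stimulus, so the detector subtracts this known filter
  delay; on a noiseless ramp the boundary lands on the ramp end, and with
  0.05 °C thermocouple noise it stays within 0.5 s of it.
* **Responder classification**: a deterministic feature-based time-series
  classifier (logistic regression over baseline-z-scored amplitude, SNR,
  transient-template correlation and early/late balance of the 4
  Hz-downsampled per-stimulus trace), trained on labelled synthetic traces
  that mirror the hand-labelled training sample of the original analysis.
  This replaces a convolution-kernel time-series classifier with an
  interpretable model under the same input/output contract; identical
  inputs give identical calls.  Held-out balanced accuracy at the default
  SNR is ≥ 0.95.  Capsaicin and KCl epochs are called by a robust
  amplitude criterion (their responses are large); cells responding to no
  applied stimulus are excluded from all tables.
* **Onsets**: first time within the stimulus at which ΔF/F0 exceeds 10% of
  its in-stimulus maximum, labelled dynamic/static by the phase boundary.
  Onset detection runs on the 4 Hz per-stimulus trace with a light (0.75 s)
  moving average: at full rate the 10% threshold sits ~2 noise SDs above
  baseline and first-crossing statistics would fire early on noise.
* **Cell ordering** (heat maps): ascending first crossing of 10% of each
  cell's *cumulative* session ΔF/F0 — deliberately distinct from the
  per-stimulus onset rule; ties keep the original order, non-positive
  totals sort last.
* **FOV statistics**: responder proportions relative to KCl-viable cells
  and the mean trapezoidal AUC of ΔF/F0 over each stimulus epoch among that
  stimulus's responders.

## 7. What the synthetic data does and does not show

The generators reproduce the statistical structure the analysis assumes:
DDM-distributed visit durations with genotype/chamber cells, animal random
effects and end-of-session censoring; keypoint noise, dropout and climbing;
stimulus-locked transients with known onsets, neuropil contamination,
bleaching and shot noise.  Passing tests therefore demonstrate that the
pipeline recovers the truth *when the model family is correct*.  They do
not validate the DDM as a description of real mouse behaviour, nor the
classifier against real hand-labelled traces (kinematics, correlated
noise, overlapping cells and z-drift are not modelled), and the absolute
parameter scale (σ = 1 convention) is not comparable across packages
without accounting for their σ convention.

## 8. Problem sizes used in the shipped checks

Chosen to estimate each quantity tightly: density/simulator agreement at
1e5 paths per grid cell; hierarchical recovery with 2 genotypes × 20
animals × ~100 visits (the scaled 2 × 500/500 sampler) over 20 replicates
in the test suite and 6 replicates in `scripts/acceptance.py`; 50 sessions
for the trajectory round trip; 8 FOVs × 300 cells for responder-fraction
recovery; 100 noisy stimuli for the phase boundary.

## 9. Known limitations

* The per-cell ("predictor") boundary separation mode is not implemented.
* The HMC sampler is not a full no-U-turn implementation; on strongly
  multimodal posteriors (outside this model family) it would need manual
  tuning.  Diagnostics are always reported and flagged.
* PSIS-LOO tail estimates are noisy at the scaled draw counts; reliability
  flags should be read per run.
* The exact CV-versus-sv law of the absorption-time distribution reverses
  in the diffusion-dominated regime (small v·a); see the density moments
  for v = 0.5, a = 1 — inter-trial drift variability only widens visit
  lengths when drift carries the passage.
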