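# Methods

## Scope and data flow

The package quantifies presynaptic dopaminergic function from framed dynamic
[¹⁸F]FDOPA PET using the reference-tissue Patlak method, and analyses a
unilaterally lesioned cohort in which each animal carries three severity
measures: the bilateral influx constants *K*ᵢ, striatal dopamine-plus-
metabolite content, and methamphetamine-induced rotation counts. No real
acquisitions ship with the package; a synthetic module generates every input
with known ground truth, which is what makes the chain testable end to end.

Stages: framing → (decay correction → SUV) → VOI-mean TAC extraction →
Patlak transform and OLS fit → asymmetry ratios → cohort assembly →
paired *t* / ANOVA + Dunnett / regressions.

## Acquisition model

* **Framing.** Frames are contiguous, first start at 0; the default scheme
  is `6x10,6x30,11x60,15x180,3x600` (41 frames, 90 min). All kinetic
  computation represents a frame by its mid-time.
* **Decay correction** multiplies frame values by 2^((t_mid − t_ref)/T_half)
  with T_half = 109.77 min (physical constant of ¹⁸F) and reference time =
  injection time, which coincides with scan start. The operation is exactly
  invertible.
* **SUV** = concentration (kBq/mL) × body weight (g) / injected activity
  (kBq), tissue density taken as 1 g/mL. Because target and reference are
  scaled identically, the Patlak slope and intercept are invariant to
  whether SUV or raw concentration feeds the fit; the pipeline records which
  was used. Defaults (55 MBq into a 440 g rat) sit mid-range of a
  108–151 MBq/kg dosing scheme.
* **VOI extraction** is the plain unweighted arithmetic mean over voxels
  carrying a mask label — no partial-volume weighting. Note that the mean of
  *n* bit-identical voxel values can differ from the region value in the
  last 1–3 ulp; round trips are exact to ~1e-15 relative, not bit-exact.

## Forward simulation

* **Plasma input.** A(t) = A·t·e^(−λ₁t) + B·(1−e^(−λ₁t))·e^(−λ₂t), defaults
  A = 300 kBq/mL/min, λ₁ = 4 min⁻¹ (first-pass peak near 15 s), B = 30
  kBq/mL, λ₂ = 0.025 min⁻¹ (terminal half-life ≈ 28 min). The slow term is
  gated by (1−e^(−λ₁t)) so the curve rises from zero at injection, as a
  bolus must. The analysis itself never consumes the plasma curve — it
  exists to drive the forward model and to let the reference-tissue
  approximation be characterised.
* **Tissue model.** The two-tissue irreversible system above, integrated
  with an adaptive stiff solver (rtol 1e-10) with an augmented state that
  accumulates ∫(C_free+C_trap), so each frame value is the *frame-duration
  average* — what a scanner histogram measures — rather than a mid-point
  sample. With k3 = 0 this is the one-tissue reference model.
* **Default kinetics.** Cerebellum K1 = 0.5 mL/min/g, k2 = 0.5 min⁻¹
  (distribution volume 1, so the reference-based Patlak slope estimates the
  plasma-input macro-parameter directly); striatum K1 = k2 = 0.4 with k3
  solved per animal from the target *K*ᵢ via k3 = K_i·k2/(K1 − K_i).
* **Accuracy of the reference approximation.** The reference-tissue slope
  carries two small biases: a multiplicative factor ≈ (k2′ − λ₂)/K1′ from
  the reference region tracking a decaying (not constant) plasma tail, and
  an additive offset from the residual equilibration transient of the target
  free compartment inside the 10–60 min window. The additive term is roughly
  independent of k3, so its *relative* impact grows as *K*ᵢ shrinks: with
  striatal k2 = 0.25 min⁻¹ recovery of a severe-lesion *K*ᵢ ≈ 0.005 min⁻¹
  errs by ~8%, while with k2 = 0.4 min⁻¹ (equilibration half-time ≈ 1.7 min,
  fully resolved by the 10-min window start) recovery is within ~2% at every
  severity — hence the k2 = 0.4 default. The 5% recovery guarantee asserted
  in the tests is conditioned on k2 + k3 ≥ 0.35 min⁻¹; near k2 + k3 = 0.2
  it holds for intact-striatum influx values but not for severely lesioned
  ones.
* **Phantom.** Labelled boxes (left/right striatum, cerebellum) on a
  24×24×18 grid of 1.2 mm voxels; voxel noise is Gaussian with
  SD = noise_cv·value/√(duration/mean duration), mimicking count statistics
  (shorter frames are noisier) without projection-space simulation; negative
  draws clip to zero. No attenuation, scatter or reconstruction modelling.

## Patlak conventions

* Running integral of the reference: trapezoid on frame mid-times with an
  initial triangle from (0, 0) to the first mid-time. The exact-identity
  generator (`construct_patlak_exact_tac`) uses the same rule, which is why
  its round trips recover (K_i, V) to ~1e-15 — machine precision, not model
  accuracy. A consequence of the triangle closure: for a constant reference
  the normalized time is t − t₀/2 past the first frame, not t itself.
* Window membership is a closed interval on mid-times, default [10, 60] min;
  frames after the window are ignored in fitting but retained for plotting.
* Unweighted ordinary least squares (no frame-duration weights), matching
  common kinetic-software defaults. Conventions are written into output
  metadata because other implementations may use frame starts or open
  windows.

## Cohort generator

The generator encodes the study conditions of a 6-OHDA dose-response design:

* group sizes {0 µg: 3, 7 µg: 6, 14 µg: 6, 28 µg: 6} (the PET arm);
* intact-side *K*ᵢ ~ N(16.2, 0.25²)×10⁻³ min⁻¹, matching the reported
  intact-striatum range (15.7–16.7×10⁻³ min⁻¹);
* residual ipsilateral fraction s per dose from a truncated normal on
  (0, 1] — means (1.0, 0.70, 0.55, 0.32), SDs (0.02, 0.20, 0.20, 0.04):
  tight at 0 and 28 µg, widely scattered at the intermediate doses, as the
  dose-response data show; 28 µg centred so K_i R/L falls in the reported
  25.0–39.5% band. The truncated-normal family itself is a modelling choice
  (no distribution is reported) and is config-exposed.
* monoamine link: DA R/L% = 1.2·(K_i R/L%) − 20 + N(0, 8²), clipped to
  (0, 100] — a line through (≈32%, ≈18%) and (100%, 100%), consistent with
  a severity relation that does not pass through the origin (the influx
  signal retains non-dopaminergic decarboxylation sources at full
  denervation); absolute intact-side content 75 ± 8 nmol/g.
* rotation link: log₁₀(rotations) = −0.035·(K_i R/L%) + 4.0 + N(0, 1²) for
  lesioned animals (≈750 turns/90 min at R/L 32%, ≈35 at R/L 70%); controls
  draw from Poisson(3) instead, because unlesioned animals rotate
  negligibly and a log-linear link has no sensible control limit. Counts
  are rounded to integers; this quantisation (plus the +1 offset in
  log₁₀(count+1)) is why the noise-free rotation correlation approaches ±1
  only in the large-count limit, whereas the noise-free monoamine
  correlation is exactly 1.

With these defaults the emergent cohort statistics — ANOVA F on the
ipsilateral *K*ᵢ, and the three pairwise correlations — come out near the
magnitudes such studies report; they are properties of the configured
conditions, not fitted targets. The clip of DA R/L to (0, 100] censors the
linear link when a group's severity distribution crosses the link's range
limits; parameter-recovery checks therefore use severity distributions ≥3 SD
inside the in-range band.

What the generator does **not** emulate: radio-metabolite species, partial
volume and spill-over, animal motion, attenuation/scatter, reconstruction
artefacts, inter-animal kinetic variability in the reference region, or any
deviation from linearity in the severity links. Passing tests show the
estimation chain is correct under the stated model, not that real scans are
free of these effects.

## Statistics

* Paired *t* (two-sided, df = n−1) on within-animal differences; one-way
  ANOVA with F = MS_between/MS_within on (k−1, N−k) df; OLS regression with
  Pearson r and the two-sided p from t = r·√((n−2)/(1−r²)). All tests
  two-sided at α = 0.05 (sidedness is a package convention).
* **Dunnett's post hoc** is computed by seeded Monte Carlo: per-group
  t_i from the variance pooled over *all* groups (df = N−k), and the
  family-wise adjusted p = P(max_j |T_j| ≥ |t_i|) under the joint
  multivariate-t null with correlation ρ_ij = √(n_i n_j/((n_i+n₀)(n_j+n₀)))
  induced by the shared control. Monte Carlo (default 10⁵ draws, ~±0.003
  standard error on p near 0.05) is used instead of tabulated critical
  values because the design is unbalanced (control n = 3 vs treatment n = 6).
  Adjusted p values are floored at the single-contrast p, a mathematical
  lower bound a finite-sample Monte Carlo estimate can dip below.
* Rotation counts enter regressions as log₁₀(count + 1); the unit offset
  keeps zero-rotation controls finite and is recorded in output metadata.
* Degenerate inputs (zero difference variance, zero pooled variance,
  constant regressor) raise errors rather than returning NaN; zero
  within-group variance with unequal means reports F = ∞ explicitly.
* The correlation stage is complete-case: animals missing any of the three
  measures are excluded by inner join and logged. The paired-t and ANOVA
  stages use all animals available for their measure, so the per-stage n can
  differ, as in real cohorts.

## Problem sizes and determinism

Default cohort 21 animals; link-recovery checks use 200 animals/group; the
ANOVA null calibration uses 10⁴ replicates; the Dunnett cross-validation
oracle uses 10⁶ data-level simulations. The full test suite runs in well
under a minute on one CPU. Every random draw flows from one integer seed
per run (sub-seeds via `numpy` SeedSequence), and output tables embed the
seed and a config hash, making all outputs byte-reproducible.

## Known limitations

* The Patlak estimate inherits the reference-tissue biases quantified
  above (≲2% in the default regime); no plasma-input or Logan analysis is
  provided.
* Masks are taken as given; no coregistration, ROI drawing or motion
  handling.
* The rotation-count model is a stand-in: no published distributional
  information exists beyond log-scale scatter, so only its link structure
  (log-linear in severity, negligible control rotation) should be relied on.
* Dunnett p-values carry Monte Carlo error (standard error ≈ √(p(1−p)/draws));
  raise `n_draws` where 3-decimal stability is needed.
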