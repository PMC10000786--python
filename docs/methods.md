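# Methods

`stratify` analyzes dynamic epifluorescence near-infrared (DE-NIR) videos
of tumor-bearing rodents after an intravenous indocyanine-green (ICG)
bolus, and classifies the host vasculature's Dll4 expression class (high
vs low) from the kinetics of the tumor's time-intensity curve. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic study conditions do and do not establish.

## The analysis pipeline

1. **Preprocessing.** The mean of the pre-injection frames (≈5 s before
   the bolus; camera offset plus excitation-light leakage) is subtracted
   from every frame and negative residuals are clipped at zero, since
   intensities are photon counts. Respiratory motion appears as
   high-frequency intensity jitter in each pixel's kinetic sequence; it is
   removed per pixel along time by a zero-phase (forward–backward)
   4th-order Butterworth low-pass combined with 1-D wavelet shrinkage
   (db4, soft universal threshold, noise scale from the finest detail
   level's median absolute deviation). The default cutoff of 0.8 Hz sits
   below rodent respiratory rates (~1–2 Hz) and above the ICG kinetics
   bandwidth (~0.1 Hz). Rigid registration to a reference image maximizes
   the phase-correlation score of the temporal-mean image over a rotation
   grid (±10°, 1° steps, parabolic refinement) followed by sub-pixel
   translation estimation; the reported transform is the correction
   applied to the stack.

2. **ROI detection.** The stack is unfolded to a pixels × frames matrix,
   mean-centered per pixel, and decomposed by SVD (PCA along the time
   dimension): per-pixel scores form spatial loading images in which
   organs with shared kinetics appear as coherent patterns. Because PCA
   signs are arbitrary, each component is flipped so its image's 99th
   percentile is positive, and ranking against a tumor-containing
   reference image uses the maximum *absolute* normalized 2-D
   cross-correlation — which also makes the ranking invariant to affine
   rescaling of the reference. Segmentation of the chosen component
   locates the reference's foreground template by 2DCC (bounding box =
   per-reference boxes averaged), then applies grey-scale morphological
   dilation (disk radius 2 px), Otsu thresholding inside the box, and
   largest-connected-blob extraction; if the signed correlation at the
   peak is negative the component image is inverted first, since the tumor
   can appear as a dark structure in a liver-dominated component. No real
   reference images were ever deposited, so the package ships a generator
   for synthetic tumor-shaped references and accepts user-supplied ones.

3. **Kinetic features.** Each ROI's mean-brightness series is smoothed
   with a Savitzky–Golay filter (order 3, window 31 frames) and min–max
   normalized. The peak is the first global maximum. The latency (dye
   arrival) is the last robust zero crossing of the smoothed first
   difference before the peak — the last frame whose difference turns
   positive and stays positive for ≥ `robust_len` (default 5) frames —
   followed by a level refinement that advances the anchor to the last
   frame within 1 % of the peak value above the crossing level.
   The refinement matters because smoothing correlates the baseline noise
   over ~one window, so the difference can stay positive through a flat
   pre-arrival stretch; without it, latency estimates have second-scale
   outliers. On the default generator the detector recovers latency and
   TTP with mean absolute errors of ~0.1–0.2 s (tested).

   From the landmarks, 43 base quantities are computed (times in seconds;
   indices via `round(seconds × fps)`, out-of-range indices clipped to the
   last frame with a logged warning):

   - `TTP` (time to peak from latency), `U = (1 − I(L))/TTP`,
     `TR = TTP / (t_halfmax − t_L)`;
   - downslopes `D_S = (1 − I(peak + S))/S` and half-intensity-forward
     slopes `HIF_S = (1 − I(halfmax + S))/S` for
     S ∈ {2,4,5,6,8,10,12,14,16,18,20,23,25,30,35,40,50,60,70,80} s.

   Each quantity has a plain variant (`_rel`) and a window-robustified
   variant (`_avg`): D/HIF take the median of the full D(S+s)/HIF(S+s)
   (shifted index *and* denominator) over anchor offsets
   s ∈ {−1.5, −1.3, …, 1.5} s, and TTP/U/TR take the median over the same
   offsets applied to the latency anchor. This yields 43 × 2 = 86 features
   per ROI. The per-animal vector relates tumor to healthy tissue:
   `Fn = (F_tumor − median(F_fatpad)) / median(F_fatpad)` over the 3–4
   mammary-fat-pad ROIs (medians are taken over finite values; a zero or
   undefined fat-pad median flags the feature missing). Because the series
   is normalized before any feature is computed, the whole vector is
   invariant to rescaling the raw intensities (tested).

4. **Classification.** Models: nearest neighbors, linear SVM, RBF SVM,
   decision tree, Gaussian naive Bayes, logistic regression — all via
   scikit-learn behind one registry, with input standardization and small
   fixed hyperparameter grids (reproducibility over exhaustiveness).
   Models that support it use balanced class weights: strain groups differ
   in size up to 28 vs 12, and the headline `A_score = (accuracy +
   sensitivity + specificity)/3` averages both class-conditional rates, so
   unweighted fits would systematically sacrifice the smaller group.
   Neural networks are deliberately excluded. The positive class is
   always Dll4-high. A generalized additive model is listed in the
   original suite; it is omitted here because no GAM backend is among the
   package's dependencies and the core results use SVM/KNN/DT.

   *Pair evaluation* repeats a stratified 75/25 split `n_repeats` times
   (default 20), tunes each model by inner stratified CV on the training
   part (fold count capped at the smallest class count; candidates ranked
   by out-of-fold A_score), and reports the test-set metric panel. Both
   the best and the mean A_score across repeats are always computed; the
   two-stage selection reports the best for stage 1 and means thereafter,
   mirroring the original protocol's usage.

   *Pair selection* is two-staged over the congenic pairs eligible under
   n > 5: stage 1 computes all-feature separation scores
   `S = (A(Dll4+|CG−) + A(CG+|Dll4−) + 2A(CG+|CG−))/4` and keeps pairs
   with S > 0.80; stage 2 scores survivors with their two best recursive-
   feature-elimination features and keeps A ≥ 0.70, selecting the argmax
   (ties broken lexicographically, logged). Stage-2 scores come from
   repeated stratified k-fold CV (k = min(6, smaller class), 6 fold
   shuffles) with RFE nested inside every fold and the confusion matrix
   pooled per repetition: feature selection never sees its test fold, so
   the score is free of selection optimism, and every animal is tested
   once per repetition, which keeps the estimate stable for 12-animal
   groups. The *reported* feature pair for downstream use is RFE on the
   pair's full data. RFE eliminates features one or more at a time (30 %
   of the remainder above 10 features, then singly), ranking by
   coefficient magnitude (linear models), impurity importance (trees) or
   permutation importance (others); constant columns are dropped first.

   *Final evaluation* first refines the final feature pair by RFE on the
   pooled parental + selected congenic groups (high: Dll4+ and CG-high;
   low: Dll4− and CG-low) — pooling the strongest-contrast groups selects
   features carrying the class axis itself rather than pair-specific
   quirks, and transfers measurably better to the held-back groups than
   pair-only RFE features. It then pools the held-back groups (all except
   the parental strains and the selected congenic pair), makes one
   stratified hold-out split (25 % for the original cohort, 20 % for the
   augmented one), tunes, and reports the confusion-matrix panel, the ROC
   curve from a decision-score threshold sweep, and the trapezoidal AUC.
   Degenerate (constant) scores yield AUC 0.5 exactly.

5. **Group statistics.** The repeated-measures comparison uses subject-
   level summaries: per-strain mean curves on a uniformly decimated
   common grid (default 1400 timepoints), a response covariance pooled
   from between-subject deviations around strain means (df = subjects −
   strains), whose diagonal projected on the time axis shows *when*
   strains differ, and estimated marginal means (time-averaged subject
   means) with unequal-n standard errors from the pooled subject-level
   variance. Pairwise comparisons use the Tukey–Kramer statistic
   `q = |Δemm| / √((se_i² + se_j²)/2)` against the studentized-range
   distribution with (n_strains, df) parameters. With two groups this
   reduces exactly to the pooled-variance t-test (verified numerically).
   The original analysis fit a full mixed-effects model with time-varying
   covariates whose random-effects structure is not specified anywhere;
   this simplified estimator reproduces the same output objects
   (covariance matrix, diagonal projection, adjusted p-matrix) with a
   fully specified computation, and single-subject strains are excluded.

## The synthetic study conditions

No imaging data were deposited for the original cohort; only the rat
strain records exist. The generator therefore emulates the study design
so every stage runs against known ground truth:

- **Curve model.** Smoothstep wash-in on [latency, latency+TTP], then a
  bi-exponential wash-out `peak·(r·e^(−k_slow·Δt) + (1−r)·e^(−k_fast·Δt))`,
  plus Gaussian noise and a global ~1 Hz sinusoidal intensity modulation
  standing in for respiratory jitter (the published correction treats
  respiration as per-pixel kinetic jitter, not geometric motion, so no
  geometric warping is simulated). This is a minimal morphology model,
  not a pharmacokinetic compartment model.
- **Cohort structure.** Exactly the published group sizes: Dll4+ (8),
  Dll4− (17), CG1 (19), CG2 (2), CG3 (26), CG4 (12), CG5 (28), CG6 (12),
  CG7 (5), CG8 (4); 133 animals, each with one tumor and 3–4 fat-pad
  series at 10.6 fps. Cohort series default to 3000 frames (the full
  ~283 s acquisition), phantom videos to 64×64×600 frames with a switch
  to the full 256×256×3000 geometry.
- **Class effect.** Dll4-low hosts take up dye faster and retain it
  longer: per-group kinetic parameters interpolate along one high/low
  axis α (latency 11+1.0α s, TTP 7.5+1.5α s, slow decay 0.009+0.003α /s,
  retention fraction 0.475−0.125α; within-group sds 1.1 s, 1.1 s,
  0.0027 /s, 0.09). The washout/retention gap is what the D- and
  HIF-family features measure, so the planted effect lives exactly in
  the feature region the method advertises. Parental strains sit at
  α = ±1; CG5/CG4 at ±1.4 are the planted best congenic pair, with
  roughly three times the class-effect strength of the remaining
  congenic groups (±0.45). Strain means are *fixed*: consomic/congenic
  strains are inbred, so the genetic effect on each parameter is a
  constant and only per-animal environmental variation is random
  (group draws are re-centered on the strain mean). Curve noise sd 0.02,
  respiratory amplitude 0.02 at 1 Hz.
- **Phantoms.** Ellipse anatomy (tumor in the lower half, 3–4 smaller
  fat pads, a large liver with fast bright kinetics) rendered with a flat
  background and optional pixel noise; all pixels of one ellipse share
  the ROI's curve.
- **Augmentation.** For stacks: random rotation (default ±10°; the
  original range is unstated), horizontal flip and up to 2 % rescale with
  constant-padded interpolation. The published augmented dataset (606
  points) came from transforming raw 256×256×3000 stacks; re-rendering
  606 stacks is far beyond desk scale, so `augment_records` applies the
  footprint those transforms leave on ROI-mean series (≤2 % intensity
  rescale + small interpolation-like noise) and replicates each base
  record the minimal number of times before truncation to the target
  count. The augmentation multiplicity is exposed as a parameter because
  the original multiplicity is not stated.

**What passing tests show — and don't.** The synthetic conditions verify
that the implementation recovers what was planted: generating parameters
from curves, the tumor from phantoms (mean Dice ≥ 0.7, centroid ≤ 2 px),
the planted best congenic pair, and high hold-out AUC at the default
effect size. They do not establish that real Dll4 classes are separable
at these rates: real tissue kinetics are not bi-exponential, real
respiratory motion is partly geometric, fat pads are imperfect
references, and real strain effects are not one-dimensional. Desk-scale
problem sizes (64×64 phantoms, 3-repeat protocols with 3-fold inner CV in
the test suite) are the package's default operating point; all sizes are
parameters.

## Numerical choices and degenerate inputs

- Min–max normalization of a constant series returns all zeros (flagged
  degenerate) rather than dividing by zero.
- Ties at the curve maximum resolve to the first occurrence; `robust_len`
  defaults to 5 frames (~0.47 s at 10.6 fps).
- TTP = 0 leaves U and TR undefined (NaN, logged); a zero fat-pad median
  flags that feature missing for the animal; animals whose landmark
  detection fails are excluded from the feature table with a warning.
- Seconds→frames conversion is `round(s × fps)` everywhere.
- PCA requests beyond the matrix rank are reduced with a warning;
  reconstruction from all components reproduces the stack to ~1e−12.
- Confusion-derived rates with zero denominators are reported as 0, and
  MCC is 0 when any marginal is zero.
- Background subtraction drops the background frames and leaves
  `n_background_frames = 0`, so a second application is an invalid-state
  error by construction.
- All randomness flows from explicit integer seeds; reruns with the same
  configuration are byte-identical.

## Known limitations

- The simplified repeated-measures estimator is not a mixed-effects
  model; it cannot express within-subject serial correlation structures
  beyond what the pooled covariance captures.
- The series-level augmentation surrogate does not probe rotation
  robustness of the *imaging* stages (the stack-level transform does, and
  is tested separately).
- Separation scores reported by the original study for its real data
  (printed S-score tables) are not reproducible from first principles:
  the printed S values differ slightly from the separation formula
  applied to the printed A values (presumably unrounded inputs), and the
  underlying imaging data were never released. The package reproduces
  the formula exactly and documents the discrepancy.
- Tumor detection assumes a roughly elliptical, localized tumor whose
  kinetics differ from surrounding tissue; diffuse or multifocal disease
  would need user-supplied references or a mask override.
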