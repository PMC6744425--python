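# Methods

This note documents the models and numerical choices behind `ndba`: what the
synthetic generator simulates, how each analysis stage is defined, which
parameters matter, and what the package's self-checks do and do not show
about real data.

## Analysis model

### Classifier and distances

The classifier is Fisher's linear discriminant with a shrinkage-regularized
pooled covariance,

    w ∝ Σ̂⁻¹ (μ₁ − μ₀),   Σ̂ = (1 − γ) S + γ (tr S / p) I,

with the bias placing the boundary at the class-mean midpoint (the design is
balanced, so equal priors are assumed throughout). Shrinkage γ defaults to
Ledoit–Wolf analytic shrinkage toward the scaled identity, estimated from
the class-centered training samples; this is essential in the searchlight
regime, where 100 voxels are fit from ~64–77 samples. A fixed γ ∈ [0, 1] can
be supplied instead; at γ = 0 the fit reduces to the closed-form solution
(verified against an independent matrix-inverse oracle in the tests).

Distances are geometric: d(x) = (w·x + b)/‖w‖. Normalizing by ‖w‖ does not
affect any reported correlation (they are scale-invariant) but makes
distances comparable across cross-validation folds. For distance-to-bound
analysis the sign convention is "correct side positive": a held-out sample's
distance is positive exactly when the classifier labels it correctly, so
misclassified stimuli carry negative distances (a config flag switches to
absolute distances).

### Cross-validation

Searchlight decoding uses leave-one-run-out. Distance estimation uses a
stratified 5-fold (4/5 train) split over the per-run pattern estimates,
stratified jointly by class and run with a seeded shuffle; each sample is
held out exactly once, and each stimulus's distance is the average over the
folds in which its samples were held out. The held-out distances are also
retained per [stimulus × run] for reliability (below). A single 5-fold pass
leaves a small fold-boundary wobble (each fold's boundary shifts with the
held-out exemplars); tests document that rank recovery of planted distances
improves from ρ ≈ 0.92 (one pass) toward 1 as passes are added.

### Searchlight, group inference, ROI selection

Neighborhoods are each voxel's k = 100 nearest voxels by Euclidean distance
on the integer grid (ties broken by (z, y, x) order for determinism). The
per-neighborhood LDA fits are batched — stacked covariance construction,
vectorized Ledoit–Wolf shrinkage, and batched linear solves across
neighborhoods — so a whole-volume map costs seconds per subject. Group
inference is a per-voxel one-sample t-test of subject accuracies against
chance (one-sided), Benjamini–Hochberg-adjusted across voxels; the default
significance threshold is q ≤ 0.005 and the ROI is the ceil(10%) of
highest group-mean-accuracy voxels inside the mask. Group-level inference
and group-mean ranking were chosen (over per-subject variants) so a single
shared ROI results. Voxels where all subjects sit exactly at or below chance
with zero variance get p = 1; unanimous above-chance accuracy with zero
variance gets p = 0 — with very few subjects this convention can admit
occasional degenerate false positives, which the pipeline tolerates
(an ROI is simply reported with its size).

### Behavior scoring

LISAS for stimulus j: RT_j + (S_RT / S_PE) · PE_j, with RT_j the mean RT of
correct trials by default (`rt-basis: correct-only|all`), S_RT the SD of the
subject's trial RTs in that task, and S_PE the SD of the subject's
per-stimulus error proportions (per-stimulus rather than trial-level,
because the score is applied per stimulus). When a subject makes no errors
S_PE = 0 and LISAS reduces to mean RT. Mean RT is used inside LISAS; medians
are reported descriptively. Per-subject scores are group-averaged into one
behavioral vector per task, which is what the per-subject neural distances
are correlated against.

Subjects indistinguishable from chance on any task (one-sided exact binomial
test of overall task accuracy vs 0.5, α = 0.05) are excluded from all
analyses. The speed–accuracy diagnostic correlates per-stimulus mean RT with
proportion correct; when a common evidence variable drives both, slow
stimuli are the inaccurate ones and the correlation is negative.

### Crisscross predictor

The indoor/outdoor grouping spans both animacy and shape levels, so no
single linear boundary separates it. The predictor is
percentile(animacy distances) + percentile(shape distances), each vector
rank-scaled to [0, 100] via 100·(rank − ½)/n with mean ranks for ties —
a city-block combination in which the shared percentile scale guarantees
equal weight. Scaling is across all 32 stimuli by default
(`percentile-scope: all|category`). Within one ROI, both classifiers'
distances come from that ROI's voxels.

### Reliability and the joint ceiling

For each ROI × task × category cell, split-half reliabilities are computed
over random balanced splits of runs (all distinct splits are enumerated when
few exist — 3 runs admit exactly 3 one-vs-two splits). The behavioral half
vector re-aggregates LISAS from the half's trials and group-averages; the
neural half vector averages the corresponding run columns of the full
cross-validation's [stimulus × run] held-out distances. Distances are
deliberately *not* refit from each half alone: that would shrink the
training sets from ~77 to ~25 samples and confound estimation quality with
data quantity, systematically underestimating the ceiling.

Half correlations are corrected to full length with the Spearman–Brown
formula, generalized for unequal halves: modelling each run as signal plus
i.i.d. noise, the split correlation is 1/√((1+u/n₁)(1+u/n₂)) with u the
noise-to-signal ratio; solving for u and projecting to all runs reduces
exactly to 2r/(1+r) for equal halves. The joint ceiling is
√(r_behavior · r_neural) when the product is nonnegative and is flagged
undefined otherwise (rather than producing an imaginary number); a display
helper negates it for plotting against negative correlations.

## Synthetic study generator

The generator emulates a three-task categorization study: 32 greyscale
object stimuli in 4 clusters of 8 (pets and insects animate; tools and
vegetables inanimate; one bar-like and one blob-like cluster per animacy
level — by default pets/vegetables blob and insects/tools bar, exposed as a
config choice since either counterbalanced assignment is valid), with
indoor = {pets, tools} crisscrossing both dimensions. Per subject, 3 runs
with 2 repeats of each stimulus per run; patterns are beta-like per-run
estimates, one per stimulus per run.

Pattern model, per dimension D with planted separation a_D in its region:

    x(stim i, run r) = Σ_D (s_i a_D + e_i^D) · u_D + ε,   ε ~ N(0, σ_run² I)

where s_i = ±1 is the stimulus's class sign, e_i^D ~ N(0, σ_offset²) is a
per-exemplar offset shared across subjects and runs (the single planted
driver of within-category distance variation, which keeps parameter recovery
well-posed), and u_D is a unit direction supported on the region's voxels,
drawn per subject with random signs and equal magnitudes. Equal-magnitude
loadings give every region voxel the same information density, so the extent
of the significant searchlight shell is set by geometry rather than by the
luck of individual loadings. The per-stimulus signed true distance
t_i^D = s_i a_D + e_i^D is returned for recovery tests and behavior
generation.

Behavior, per trial:

    RT = intercept + slope · m(cat) · |t| + N(0, σ_RT),  floored at 150 ms
    P(correct) = logistic( (m(cat)·|t| + (1−m(cat))·mean|t|) / scale )

where m(cat) ∈ [0, 1] is a per-category asymmetry multiplier gating *both*
behavioral channels: a fully decoupled category (m = 0) keeps a realistic
category-typical accuracy but loses all distance dependence. Gating the
accuracy channel too is necessary because LISAS folds error rates back into
the score — with accuracy always distance-coupled, a category whose RT slope
is zeroed would still inherit distance coupling through the error penalty.
The linear RT model and logistic accuracy link are modelling choices matched
to the linear-correlation analysis; any monotone link would serve. The
crisscross task's driving distance is the city-block mean
(|t^animacy| + |t^shape|)/2.

Stimulus images are rendered ellipses: aspect ratio 2.5–3.5 for bar-like,
1.05–1.4 for blob-like, with orientation, position, intensity, and texture
jitter drawn independently of cluster — so shape is image-computable and
animacy is not, by construction.

All randomness derives from one root seed through named substreams
(exemplars / patterns / behavior-per-task / images), so each component can
be regenerated independently and every output is a pure function of
(config, seed).

### Default study conditions

8 subjects, 3 runs per task, 2 repeats per run, an 18×11×11 grid (2178
voxels) with two disjoint 150-voxel blocks (animacy signal in the
"LOC-like" block, shape in the "EVC-like" block), separation a = 4.0,
exemplar offset SD 0.5, run noise SD 1.0, RT intercept 900 ms, slope
−60 ms per distance unit, RT noise SD 150 ms, accuracy link scale 1.7, and
asymmetry {animate 1, inanimate 0, indoor 1, outdoor 0} (unlisted labels
default to 1, so the shape task couples in both categories). These values
were fixed once, by design: they put mean accuracy near 0.91 and median RTs
in the 670–780 ms range (the scale typical of speeded object
categorization), make both dimensions strongly decodable from their planted
blocks, and leave the selected top-10% ROI overlapping its planted block at
Jaccard ≈ 0.55. Two geometric facts constrain that overlap: only ~1000 of
the 2178 centers can reach a 150-voxel block with a 100-voxel neighborhood
(capping attainable Jaccard near 0.67), and separations much above 4 push
in-block accuracies to exactly 1.0, where top-voxel ranking degenerates into
tie-breaking.

## Self-check regimes

The heavier end-to-end checks run on scaled-down replicates (8 subjects, a
10×5×5 grid with 40-voxel planted regions used directly as ROIs — the
searchlight step is validated separately at full size) so Monte-Carlo loops
stay within minutes on one core:

- **Asymmetric recovery** uses the default effect sizes; the planted
  animate-only coupling is detected (negative, p < 0.05) in ≥ 80% of
  replicates, the decoupled category's mean r averages to ~0 across
  replicates, and the paired category difference (power ≈ 0.75–0.8 at these
  effect sizes) is detected in a clear majority.
- **Null calibration** zeroes all planted effects — coupling slopes,
  asymmetry multipliers, and exemplar offsets. Zeroing the offsets matters:
  they are shared across subjects, so under a behavior-only null the
  subjects' correlations share a common stimulus-driven component and the
  group t-test (subjects as the only random factor, exactly as the analysis
  is defined) becomes anticonservative. This stimulus-as-fixed-effect
  limitation applies to the real analysis too and is the reason occasional
  "significant" correlations appear in uncoupled cells of single runs.
- **Crisscross combination** and the **noise ceiling** run at strong
  coupling (slope −150/−120, RT noise 60/20 ms, offset SD 0.7; the ceiling
  check uses 6 runs so balanced equal splits exist). At high coupling the
  observed |mean r| presses against the ceiling, which is exactly the regime
  in which a downward-biased ceiling estimate would be exposed.

## What passing tests do and do not show

The generator plants exactly the structure the analysis assumes: Gaussian
noise that is i.i.d. across voxels and runs, signal confined to compact
boxes, exemplar effects perfectly shared across subjects and aligned with
the discriminant direction, and behavior driven by the same latent distances
with linear/logistic links. Real fMRI data violate all of these (spatially
and temporally correlated noise, distributed and subject-variable signal,
attention and motor confounds, non-stationary behavior), and the generator
makes no attempt at hemodynamics, GLM estimation, or brain geometry.
Passing recovery tests therefore certify the *pipeline* — that each stage
computes what it claims and that planted effects of realistic size are
recovered with correct sign, calibrated nulls, and consistent ceilings —
not that any particular real dataset will show these effects.

## Numerical and degenerate-input policies

- Zero-variance vectors in a correlation: the subject/split is excluded
  with a warning rather than propagating NaN.
- Degenerate group tests (all values equal): t = ±∞ with p = 0 when the
  common value is nonzero, t = 0 / p = 1 at zero; float tolerances guard
  near-equal cases.
- Searchlight neighborhoods that fail to fit yield NaN map entries and are
  excluded from ranking; a chunk failure never aborts the map.
- Empty significant mask: ROI selection raises a dedicated error and the
  pipeline records the skip per dimension, continuing with the rest.
- All-equal percentile input maps to 50; Spearman–Brown clamps at the −1
  boundary with a warning; a negative reliability product yields an
  explicit undefined flag.
- Behavioral cells with no usable RT trials (e.g. no correct trials under
  correct-only basis) are flagged NaN and skipped in group averages.
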