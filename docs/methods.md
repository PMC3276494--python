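# Methods

This note documents the models and procedures implemented in `mimsseg`,
the parameters that matter, the numerical choices behind them, and what
the synthetic fixtures do and do not establish.

## The segmentation model

Pixels of a MIMS image are classified independently from a feature
vector that carries no positional information. For each selected plane —
a raw mass channel or a scaled ratio image (`scale · m₁/m₂`, default
scale 10000, pixels with zero denominator marked invalid and set to 0) —
four features are computed:

1. the intensity value itself;
2. the mean of the (2r+1)×(2r+1) neighborhood;
3. the population standard deviation of that neighborhood;
4. the Sobel gradient magnitude.

**Neighborhood radius** `r` defaults to 1 (a 3×3 window). Larger radii
trade spatial resolution for noise suppression in low-count data; a
per-plane override exists because different masses can differ by orders
of magnitude in counting statistics. **Edge policy:** neighborhood
statistics use truncated windows (the window is intersected with the
image; corner pixels average 4 values at r=1), the gradient uses reflect
padding. Both choices are explicit because alternatives (zero padding,
wrap) bias edge features in image-dependent ways. The SD is the
population SD; window statistics are computed with a summed-area table
after centering on the global plane mean, which keeps the
`E[x²]−E[x]²` identity accurate to ≈1e-12 even for near-constant
windows.

Features are affinely mapped to [0,1] per column using the training
minima/maxima (RBF kernels are scale-sensitive); constant columns map
to 0, and test data may extrapolate outside [0,1] — nothing is clipped.

The classifier is a C-SVM with RBF kernel `exp(−γ‖x−x'‖²)` and libSVM's
one-vs-one multi-class scheme (via scikit-learn): K classes yield
K(K−1)/2 pairwise machines; each casts one vote, overall ties resolve
to the lowest class label, and a pairwise decision value of exactly
zero votes for the lower label of its pair, so prediction is fully
deterministic. No class weighting is applied: expert annotations are
used as-is, unbalanced as they typically are.

## Hyperparameter tuning

The objective is overall accuracy under stratified k-fold
cross-validation (default 5 folds); the fold assignment is fixed by the
tuning seed, so the objective is a deterministic function of
(log₂C, log₂γ).

- `tune_grid` evaluates an explicit grid exhaustively; the default is
  the conventional libSVM lattice C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} in
  steps of 2² (110 points). Accuracy ties break toward smaller C, then
  smaller γ (a weaker-regularization model is never preferred without an
  accuracy gain).
- `tune_nelder_mead` runs a standard Nelder-Mead simplex
  (α=1, γ=2, ρ=σ=0.5) over (log₂C, log₂γ), started at (0, −log₂d) with
  unit edge (d = feature count — the gamma heuristic scikit-learn also
  uses), with up to 2 restarts from the best point at halved edge
  length. Evaluated points are cached; `max_evals` (default 60) bounds
  distinct evaluations, so SVM fits = folds × evaluations. The search is
  a heuristic and can stall in local optima; on the synthetic study
  fixture it reaches the 110-point grid's CV accuracy with 22
  evaluations (110 fits vs 550 — a 5× fit reduction; sparser simplex
  budgets against denser grids widen the factor).

## ROI derivation

Connected components of the predicted label map (8-connected by
default; 4-connected available) become ROIs, after absorbing every
component smaller than `min_size` pixels (default 20) into the neighbor
it shares the longest boundary with. Boundary length is counted in
4-adjacent pixel pairs, falling back to diagonal adjacency for
components touching only diagonally; ties go to the lower class label.
Absorption proceeds smallest-component-first with components recomputed
after each merge, so the result is a fixed point independent of
processing order. Unclassified pixels (label 0) neither absorb nor get
absorbed. A component enclosed inside another keeps its own pixels —
the surrounding ROI's pixel set simply excludes the hole — so the
output ROIs partition exactly the labeled pixels.

## Validation machinery

Per class C, recall = N*_C/T_C and precision = N*_C/(N*_C+N°_C), with
N*_C the correctly-predicted pixels of C, N°_C the false positives and
T_C the expert pixels of C. Undefined values (T_C = 0, or no pixel
predicted as C) are recorded as NaN and excluded from summaries rather
than coerced to 0, which would understate small classes.

Two repeated random sub-sampling schemes split annotations, keeping
relative training amounts between classes constant: *pixel sampling*
pools all annotated pixels per class and draws ⌊fraction·n_c⌋ (at least
1, at most n_c−1) individuals; *ROI sampling* assigns whole expert ROIs
to one side, at least one per class on each side. Each iteration
re-fits the feature scaling and (by default) re-tunes (C, γ) by
Nelder-Mead on its own training half, which reproduces the long lower
tails such pipelines show when the heuristic occasionally lands on poor
hyperparameters; a fixed (C, γ) can be supplied for speed.

The *robustness* analysis first trains on 100% of the annotated pixels
and classifies the whole image — the *reference prediction* — then, per
fraction and iteration, trains on a pixel-sampled subset and computes
per-class recall of the new full segmentation against the reference.
At small fractions a class may have fewer pixels than CV folds; the fold
count then shrinks to the smallest class size (floor 2) instead of
aborting the analysis. At fraction 1.0 the reference fit is reproduced
exactly, giving recall 1 identically.

Cross-segmentation comparisons (`compare_segmentations`) treat the
second label map as truth and accept an optional label translation for
models trained with extra classes; untranslated predicted classes are
reported rather than silently dropped.

## Homogeneity test

For a class's pixel set the statistic is `h = |Mean − Sum|` with
`Mean = (1/N) Σ m₁ᵢ/m₂ᵢ` (unweighted mean of per-pixel ratios, unscaled)
and `Sum = Σm₁ᵢ / Σm₂ᵢ` (the set collapsed to one measurement).
Algebraically `Sum` is the m₂-weighted mean of the pixel ratios, so
h = 0 exactly when ratios do not co-vary with denominator counts — in
particular for any single-population (homogeneous) ratio field — and a
gross discrepancy indicates at least two populations.

The null distribution translates every ROI of the class independently
to a uniformly random position, fully inside the image and (by
rejection) outside an optional exclusion mask, preserving ROI number,
shape and size; h is recomputed over the union of translated pixels
(overlapping pixels counted once). The p-value is the left tail,
`#{h_null ≤ h_obs}/n_perm` (default 10000 permutations): *low* p means
the observed pixel set is more homogeneous than randomly placed copies.
Nominal p = 0 is reported as such; a `plus_one` flag switches to the
bias-corrected `(k+1)/(n+1)` estimator. Ties count as ≤. Pixels with
zero denominator counts are excluded from h everywhere (with a warning
when observed pixels are dropped). Translations are rejection-sampled
rather than wrapped toroidally so a translated ROI never straddles the
image border; the rejection budget is 10× the feasible offset grid,
after which a placement error names the ROI.

Calibration: when the observed ROIs are themselves placed by the same
uniform-translation law on a heterogeneous image, the test's p-values
are approximately uniform and the type-I error at α = 0.05 matches the
nominal rate (checked over 100 independent fixtures in the acceptance
suite; the +1/(n+1)-free estimator makes p very slightly conservative
at the grid resolution 1/n_perm).

## Synthetic fixtures

SIMS detectors count individual ions, so the generator uses Poisson
shot noise: a pixel of class c draws denominator counts
m₂ ~ Poisson(λ_c) and numerator counts m₁ ~ Poisson(r_c·λ_c), with r_c
the class's true isotope ratio and λ_c its mean count level. Defaults
emulate a ¹⁵N tracer study: r = (0.004, 0.05, 0.12, 0.25, 0.45, 0.8)
from natural abundance (≈0.0037) to strong enrichment, λ = (500, 420,
340, 270, 210, 160) counts — classes separated by ≥5 single-pixel-ratio
standard errors after 3×3 smoothing, i.e. the "well-separated" regime.
Geometries: horizontal bands, a Voronoi mosaic (seed points
rejection-sampled to a minimum pairwise distance so every cell can host
annotation ROIs at any seed), and disks on background. Annotations are
disk ROIs placed fully interior to their class (margin ≥ 2 px from
borders), disjoint, labeled with the true class.

What the fixtures do **not** emulate: histological structure,
instrument drift, detector dead time, correlated noise between masses,
and expert inconsistency. Passing the acceptance suite therefore shows
that the pipeline recovers known structure under ideal counting noise —
it does not bound performance on real acquisitions, where class overlap
in feature space (as between visually similar classes) is the dominant
error source.

## Problem sizes and determinism

The acceptance suite and `scripts/acceptance.py` use a 128×128, 6-class
Voronoi fixture with 3 disk ROIs (radius 4) per class (882 annotated
pixels): 50 sub-sampling iterations at fraction 0.2, 20 robustness
iterations per fraction {0.5, 0.25, 0.1, 0.05}, 2000 permutations for
the observed-ROI homogeneity test and 100×200 for its calibration —
sizes chosen so the whole analysis runs in minutes on one CPU while the
Monte-Carlo error of every reported summary stays well inside the
margins being tested. Every random choice (fixture, splits, folds,
simplex path, permutations) derives from one integer seed;
`numpy.random.Generator` streams are spawned per component, and model
files store the exact scaled training set so a reloaded model
reproduces predictions bit-exactly (libSVM fits are deterministic).

## Known limitations

- Segmentation is per-pixel; volumes are segmented slice-wise and no 3-D
  connectivity or region splitting is attempted.
- The Nelder-Mead tuner offers no global-optimality guarantee; repeated
  evaluations (as in `subsampling_eval`) average over its failures.
- `h` is a two-population discrepancy detector, not a full distribution
  test: ratio mixtures uncorrelated with denominator counts can leave
  h ≈ 0.
- p-values across classes are reported raw, without multiple-testing
  correction.
- The model file stores the training set; for very large training sets
  a native serialized SVM would be more compact.
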