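# mimsseg

Semi-automatic, SVM-based segmentation of multi-isotope imaging mass
spectrometry (MIMS) images.

MIMS couples secondary ion mass spectrometry with parallel detection of
several atomic masses: every pixel of an image holds the ion counts of
each measured mass (e.g. ¹²C¹⁴N⁻ and ¹²C¹⁵N⁻ in a ¹⁵N stable-isotope
tracer experiment). The quantity of biological interest — local isotope
enrichment, hence e.g. protein turnover — is the pixel-wise ratio of two
mass channels, conventionally scaled ×10000. Analysis proceeds by
collecting statistics over regions of interest (ROIs), which are
traditionally drawn by hand, a slow and incomplete process. `mimsseg`
replaces most of that hand-work: an expert annotates a few example
regions per class, a support vector machine learns the classes from
per-pixel features, and the whole image (or a series of related images)
is segmented automatically.

The package is aimed at MIMS/SIMS practitioners and at image-analysis
developers who need a reproducible, scriptable reimplementation of this
classic pipeline, including its validation machinery.

## What it computes

**Features.** Each pixel is described by 4 features per selected image
plane (a mass channel or a ratio image): the intensity value, the mean
and population standard deviation of the (2r+1)×(2r+1) neighborhood
(default r=1), and the Sobel gradient magnitude. No positional
information enters the feature space, which is what lets one model
segment other images of the same kind (*cross-segmentation*, F^X(Y)).

**Classifier.** A C-SVM with RBF kernel and one-vs-one multi-class
voting (K classes → K(K−1)/2 pairwise machines). Features are min-max
scaled to [0,1] on the training data. Hyperparameters (C, γ) maximize
stratified k-fold cross-validation accuracy, searched either on the
conventional 11×10 log₂ grid or — with roughly 5–25× fewer SVM fits —
by a Nelder-Mead simplex over (log₂C, log₂γ).

**ROIs.** Connected components of the predicted label map become ROIs;
components smaller than a user threshold are absorbed into the neighbor
sharing the longest boundary, and an enclosed component keeps its own
pixels, so ROIs never overlap.

**Validation.**
- per-class *recall* `N*_C / T_C` and *precision* `N*_C / (N*_C + N°_C)`
  over repeated random train/test splits of the annotations (pixel-level
  or whole-ROI sampling);
- *robustness*: recall of models trained on shrinking fractions of the
  annotations against the reference prediction trained on all of them;
- *homogeneity*: for a class's pixel set, the statistic
  `h_C = |Mean − Sum|`, where `Mean = (1/N) Σ m₁ᵢ/m₂ᵢ` and
  `Sum = Σm₁ᵢ / Σm₂ᵢ`; h_C is zero when the ratios form one homogeneous
  population. Significance comes from a permutation null that randomly
  translates each ROI of the class (shape-preserving, inside the image,
  outside an optional exclusion mask); the p-value is the left-tail
  fraction of null statistics ≤ the observed one.

Because real MIMS acquisitions of this kind are not publicly available,
the package ships a first-class synthetic generator: Poisson ion counts
with class-specific isotope ratios and count levels on known geometries
(bands / Voronoi mosaic / blobs), plus disk-shaped stand-ins for expert
annotations.

## Worked example

```sh
mimsseg synth --shape 128 --classes 6 --geometry voronoi --seed 1 \
        --out-prefix fx
mimsseg train --stack fx_stack.tif --manifest fx_manifest.json \
        --rois fx_rois.json --channels m2,m1/m2 --seed 1 --out model.json
mimsseg segment --stack fx_stack.tif --manifest fx_manifest.json \
        --model model.json --min-size 20 --out labels.tif --rois rois.json
```

prints

```
wrote fx_stack.tif, fx_manifest.json, fx_truth.tif, fx_rois.json
wrote model.json (cv accuracy 1.0000)
wrote labels.tif, rois.json (8 ROIs)
```

The synthetic mosaic has 6 classes whose ¹⁵N/¹⁴N-like ratios range from
natural abundance to strong enrichment; `train` tunes (C, γ) by
Nelder-Mead on the 588 annotated pixels (cross-validation accuracy 1.0
here because the classes are well separated), and `segment` classifies
all 16384 pixels and derives disjoint ROIs. Comparing `labels.tif`
against `fx_truth.tif` with
`mimsseg cross-segment ... --reference fx_truth.tif` reports per-class
recall/precision — recall ≥ 0.93 and precision ≥ 0.89 for every class on
this fixture, errors concentrated on class borders.

The same library API is available from Python (`mimsseg.make_fixture`,
`build_feature_matrix`, `tune_nelder_mead`, `train`, `classify_image`,
`derive_rois`, `subsampling_eval`, `robustness_eval`,
`homogeneity_test`, ...); see `docs/methods.md` for the model and its
parameters.

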