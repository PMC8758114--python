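# Methods

`discslice` implements an automated selector for the traverse lumbar-spine
MRI slice that cuts closest to the half-height of an intervertebral disc
(IVD).  The task is a 4-class image classification problem: a slice is the
mid-height slice of the L3/L4, L4/L5 or L5/S1 disc (`best_d3`, `best_d4`,
`best_d5`) or it is any `other_slices` plane.  The pipeline fuses the two
MRI contrasts of each plane into one composite image, extracts a
fixed-length feature vector with a convolutional backbone, optionally
reduces or selects features, and trains a conventional classifier or a
fully connected softmax head under Bayesian hyperparameter optimization.

## Multimodal registration

T1- and T2-weighted slices of the same plane are acquired minutes apart,
so the T2 image is aligned to its T1 counterpart before fusion.  The
discrepancy between the fixed image I_R and the warped moving image
I_T ∘ g_μ is

    S(μ) = − MI(I_R, I_T ∘ g_μ),      μ̂ = argmin_μ S(μ),

where MI is the mutual information (bits) of a joint intensity histogram
with linear partial-volume weighting into 50 bins (configurable).  The
negative sign turns Eq.-style argmin minimization and MI maximization into
the same thing.  Bin edges are frozen per pyramid level from the unwarped
image ranges so the objective does not drift as the warp moves mass in and
out of the field of view.  MI is invariant to intensity recoding, which is
what makes the metric work across the T1/T2 contrast flip.

g_μ is a 6-parameter affine transform (tx, ty px; rotation; scale_x,
scale_y; shear) acting about the image center.  The search is a
(1+1)-Evolution Strategy run coarse-to-fine over a 3-level factor-2
Gaussian pyramid with a per-level budget of 300 objective evaluations
(per-level semantics, matching the common pyramid-registration
convention).  ES parameters are scaled so one unit of any parameter moves
an image corner by roughly one pixel; steps grow by 1.05 on acceptance and
shrink by 1.05⁻¹ on rejection (stationary at a 50% acceptance rate — a
much steeper shrink makes the 6-D search collapse long before the basin is
reached).  Whenever all steps fall below 10⁻³ units the search restarts
from the incumbent with the next radius of a fixed per-level ladder (e.g.
0.5 → 0.15 → 0.05 → 0.02 at the finest level); the restarts both escape
non-optimal local minima and polish to sub-pixel precision.  An optional
3×3×3 translation×rotation grid seeds the coarsest level.

Convergence is declared when the finest-level steps collapsed at least
once, the final discrepancy did not worsen, and the final MI reaches at
least 5% of the smaller marginal entropy.  The absolute-MI test (rather
than a relative-improvement test) accepts pairs that start out aligned and
rejects unrelated images; pairs that fail are flagged, mirroring the
protocol of dropping non-converging registrations rather than aborting.

Intensity inhomogeneity is handled by a deliberately simple parametric
correction: a polynomial surface (default order 2) is least-squares
fitted to the log-intensities of the foreground, the image is divided by
the exponentiated fit, and the mean intensity is preserved.  This is a
low-order stand-in for full valley-function bias estimation and is
validated only for the multiplicative polynomial fields the phantom
generates.

## Composite images

Each registered pair becomes a 3-channel composite: channel 1 the T1
slice, channel 2 the registered T2 slice, channel 3 the per-pixel
Manhattan (L1) distance of the two — for single-channel images simply
|c1 − c2|.  Channels are normalized independently to [0, 1] with
percentile clipping at (1, 99) before differencing; robust scaling guards
against DICOM intensity outliers, and whether channels are scaled jointly
or independently is an open implementation choice made here in favor of
independence.  Composites are bilinearly resized to the backbone's square
input size.

## Feature extraction

Eleven backbone entries carry the published interface of the canonical
ImageNet architectures — input sizes (227 for AlexNet, 299 for the
Inception/Xception family, 224 otherwise) and penultimate feature widths
(AlexNet 4096, DenseNet201 1920, Inception-ResNet-V2 1536, InceptionV3
2048, MobileNetV2 1280, ResNet18 512, ResNet50/101 2048, VGG16/19 4096,
Xception 2048).  Each entry is realized as a lightweight
randomly-initialized convolutional encoder in numpy: a family-flavored
stem (11×11/4 for AlexNet, 7×7/2 + pool for the ResNet/DenseNet family,
3×3/2 stacks elsewhere), a short stack of strided 3×3 convolutions with
ReLU, and either a 1×1 convolution to the published width followed by
global average pooling (pooling families) or flatten + dense to 4096
(AlexNet/VGG).  Weights are He-initialized Gaussians fully determined by
the backbone name and a seed, so extraction is reproducible and the
feature width is an architectural property, not a constant.  Pretrained
ImageNet weights are not bundled; random-projection features of this kind
preserve geometry well enough that the synthetic study below is cleanly
separable, but no claim is made that they match pretrained-feature quality
on real MRI.  One consequence of random weights worth knowing: the
global-average-pooling families discard spatial position almost entirely
(with trained weights, position is re-encoded nonlinearly; with random
weights much less so), so for classes that differ mainly by the location
of a structure the flatten+dense families (AlexNet, VGG) are the stronger
random-weight encoders, and the end-to-end phantom benchmark uses VGG16.

## Feature reduction and selection

Three dimensionality-reduction transforms and three feature rankers are
provided, all fitted on training rows only:

- **PCA** keeps the smallest component count reaching 0.95 cumulative
  explained variance.
- **FastICA** (logcosh contrast, unit-variance whitening) and
  **maximum-likelihood Factor Analysis** reduce to a requested dimension.
- **CHI2** scores each min-max-rescaled feature by the chi-square
  statistic of its per-class mass against class-frequency expectations.
- **MRMR** greedily orders features by quantile-binned plug-in mutual
  information relevance minus mean redundancy against the selected set;
  criterion ties resolve toward the less redundant feature, then by index.
- **NCA** learns one weight per feature by maximizing the leave-one-out
  stochastic-neighbor same-class probability with an L2 penalty
  (λ = 1/n by default) via backtracking gradient ascent on weighted
  Manhattan distances, and ranks by weight magnitude.

For the non-PCA methods a representative reduced length is calibrated by
scanning 5–25% of the full width in 5% steps on an internal 80:20
holdout, taking each panel classifier's best length and snapping the
panel average to the nearest grid length.  The default panel is a
four-learner subset (LSVM, FGSVM, FTREE, WKNN) with fixed mid-range
hyperparameters — full HPO at calibration time would multiply the cost of
a step whose output is a single integer.

## Classifiers and hyperparameter optimization

The catalog declares 20 ML learner setups across five families (six KNN
variants, three decision-tree sizes, six SVMs, two discriminants, three
tree ensembles including a random-undersampling booster) with the
hyperparameter ranges of the study design (KNN neighbors 1–10/10–100/
100–1000, tree splits 4–20/20–100/100–1000, SVM kernel scales
10–40/40–80/80–160 with misclassification cost 0.001–1000, ensemble
cycles 10–50, splits 3500–4500, learning rate 0.001–0.1), plus a
multiclass-decomposition (one-vs-one / one-vs-all) and an input
standardization switch where declared.  Kernel scale σ maps to an RBF
γ = 1/σ²; a maximum split count s maps to s+1 leaves.  The three FC
setups train a single softmax layer for at most 30 epochs with SGDM,
RMSProp or Adam, searching batch size 10–20, learning rate 0.001–0.1, L2
10⁻¹⁰–10⁻², and a momentum-like decay 0.8–0.98.  The "score transform"
switch only calibrates scores and cannot change an argmax prediction; it
is recorded but inert.  Zero-padding of mini-batches is meaningless for
fixed-length feature vectors and is ignored.

Hyperparameters are chosen by Bayesian optimization of the stratified
5-fold cross-validated misclassification rate (30 evaluations by
default; CV rather than a single holdout keeps small training splits
stable).  The surrogate is a Gaussian process with an anisotropic
Matérn-5/2 kernel on normalized coordinates (log scale for
range-spanning parameters, one-hot categoricals); proposals maximize
expected improvement over a random candidate pool, and when a proposal
lands in the incumbent's immediate vicinity twice in a row the predictive
standard deviation is inflated tenfold for the next proposal — the
over-exploitation escape.  Failed or non-finite evaluations are penalized
and skipped, never fatal.  The winning configuration is refit on the full
training split.

## Evaluation protocol

With C classes, per-class precision P_i = tp_i/(tp_i+fp_i) and recall
R_i = tp_i/(tp_i+fn_i) are macro-averaged, and the macro F1 is
F = (2/C) Σ_i P_i·R_i/(P_i+R_i) — algebraically the unweighted mean of
per-class harmonic means.  A class with an empty predicted or true column
contributes 0 (with a warning); the convention is needed for small test
splits and only deflates scores.  Each method combination (backbone ×
reduction/selection × classifier) is repeated over independently drawn
stratified 80:20 splits (20 by default), with transforms and HPO fitted
on training rows only; combinations are summarized by min/max/mean/median
of each metric, the best classifier per combination is the one with the
highest mean accuracy (ties: mean macro-F1, then catalog order), and
per-class boxplot statistics are exported as numbers rather than figures.
Only the split is resampled across repeats; the augmentation is drawn
once before splitting.

## Synthetic phantom

The generator emulates exactly the structure the pipeline consumes: per
patient a 9-slice stack (slices 2, 5 and 8 carry the three mid-height
labels; interior indices are used for other stack lengths), two
modalities related by contrast inversion (T2 = 1 − T1; a gamma map is
available), a per-record affine misalignment drawn uniformly within
±6 px translation, ±5° rotation and ±3% scale, a strictly positive
order-2 polynomial bias field (±15% amplitude), and clipped additive
Gaussian noise (σ = 0.02 of the intensity range).  The anatomy is a
minimal axial-slice sketch — soft tissue and vertebral-body ellipses, a
bright spinal canal, a spinous process and two asymmetric transverse
processes, plus a bright disc/CSF annulus on mid-height slices whose
vertical position encodes the disc level at contrast 0.35.  The posterior
arch matters: without it the phantom is nearly rotation-symmetric and
image rotation is unidentifiable by mutual information.  All randomness
derives from one seed through per-record (seed, patient, slice)
substreams, so any record regenerates in isolation.  The stored
`true_transform` is the corrective transform mapping the stored T2 back
onto the T1 grid.

What the phantom does not emulate: realistic MRI texture and point-spread,
k-space or motion artifacts, 3-D geometry, inter-patient anatomical
variability beyond ellipse jitter, and the heavy class imbalance of a real
archive (quotas are exact by construction).  Passing the synthetic
end-to-end check therefore demonstrates that the machinery is correctly
wired and that the method separates classes whose differences it was told
to encode — not that real-archive accuracy would match.

## Problem sizes and numerical choices

Desk-scale defaults keep every stage exact but small: 64–128 px phantoms,
8–13 patients, 50-pair registration benchmarks, HPO budgets of 15–30,
3–20 repeats.  Registration uses linear interpolation with modal
background fill outside the domain; transforms compose and invert through
their homogeneous matrices with an R·(upper-triangular) re-decomposition.
Ranking ties break by ascending feature index (MRMR first by lower
redundancy); the 80:20 split takes the per-class floor for the test size
with the remainder training.  Degenerate cases fall back conservatively:
constant images normalize to zero, non-positive bias-field fits return
the input with a warning, Heywood cases in FA are floored by the fitting
backend, and single-class training labels raise.

## Known limitations

Random-weight encoders stand in for pretrained backbones, so absolute
accuracies on real data are not comparable to pretrained transfer
learning.  The bias correction is a low-order polynomial model, not a
full valley-function estimator.  Splits are drawn at the image level, so
slices of one patient can appear in both train and test — faithful to the
protocol being reproduced, but optimistic relative to grouped
cross-validation (a grouped splitter is exposed through the labels
argument but is not the default).  DICOM loading reads single-frame
slices with slope/intercept rescaling only; no geometric series sorting.
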