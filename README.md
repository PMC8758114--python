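# discslice

Automated selection of the traverse (axial) lumbar-spine MRI slice that
cuts closest to the half-height of an intervertebral disc (IVD).

Diagnosing lumbar spinal stenosis starts from the right image: the axial
plane through the middle of the L3/L4, L4/L5 or L5/S1 disc.  Picking those
three planes out of a patient's stack by hand takes a radiologist 30–60
seconds per study; `discslice` automates the selection as a 4-class image
classification problem (`best_d3`, `best_d4`, `best_d5`, `other_slices`)
for researchers building computer-aided-diagnosis pipelines on paired
T1/T2 lumbar MRI.

The pipeline:

1. **Registration** — the T2 slice is aligned to its T1 counterpart by
   minimizing S(μ) = −MI(I_R, I_T∘g_μ) over 6-parameter affine transforms
   g_μ with a (1+1)-Evolution Strategy (growth 1.05, coarse-to-fine
   pyramid, restart-on-collapse), where MI is partial-volume-binned mutual
   information; a polynomial bias-field correction handles intensity
   inhomogeneity.
2. **Composite** — a 3-channel image (T1, registered T2, per-pixel L1
   distance), each channel percentile-normalized to [0, 1].
3. **Features** — the penultimate-layer activation widths of 11 canonical
   CNN architectures (AlexNet … Xception), realized as seeded
   random-weight convolutional encoders in numpy.
4. **Reduction/selection** — PCA (0.95 explained variance), FastICA,
   Factor Analysis; NCA, MRMR and chi-square rankings with 5–25%
   feature-length calibration; or full-length (FL) features.
5. **Classification** — a 20-learner catalog (KNN/tree/SVM/discriminant/
   ensemble families) and a 3-optimizer softmax head, each trained under
   Gaussian-process Bayesian hyperparameter optimization with an
   expected-improvement acquisition, minimizing cross-validated
   misclassification.
6. **Evaluation** — overall accuracy A plus macro-averaged precision,
   recall and F = (2/C)·Σᵢ PᵢRᵢ/(Pᵢ+Rᵢ) over repeated stratified 80:20
   splits, with per-combination best-classifier selection.

A synthetic phantom generator (paired modalities, known affine
misalignment, bias fields, noise, four slice classes) makes the whole
pipeline testable without any data download.

## Worked example

```python
import numpy as np
from discslice.phantom import PhantomConfig, generate_study
from discslice.pipeline import pairs_to_features
from discslice.evaluate import run_benchmark, select_best
from discslice.classify import HPOConfig
from discslice.registration import ESConfig

study = generate_study(PhantomConfig(n_patients=8, image_size=64, seed=0))
print(study.label_counts())
# {'best_d3': 8, 'best_d4': 8, 'best_d5': 8, 'other_slices': 48}

features = pairs_to_features(study.records, backbone="VGG16",
                             es=ESConfig(max_iter=300, seed=0), seed=0)
print(features.values.shape)
# (72, 4096)

summaries = run_benchmark({"VGG16": features}, methods=["FL"],
                          classifiers=["FGSVM"], n_repeats=3, base_seed=0,
                          hpo=HPOConfig(budget=15, seed=0))
best = select_best(summaries)["best"]
print(best["classifier"], round(best["mean_accuracy"], 3))
# FGSVM 1.0
```

The 72 phantom pairs (8 patients × 9 slices; slices 2, 5, 8 of each stack
are the mid-height slices) are registered, fused, encoded into 4096-wide
VGG16-interface features, and classified with a fine Gaussian SVM whose
kernel scale and cost are chosen by Bayesian optimization; the mean
held-out accuracy over three 80:20 repeats is 1.0 on this cleanly
separable phantom configuration.

A thin CLI mirrors the library: `discslice phantom`, `discslice dataset`,
`discslice register`, `discslice benchmark --config bench.yaml --out out.json`.

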