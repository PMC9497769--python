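# Methods

## Problem

During complete mesocolic excision, the surgeon must separate tissue to be
resected (colon and its mesocolon) from tissue to be preserved (the
retroperitoneum, which carries the ureter and gonadal vessels).
Hyperspectral imaging (HSI) records a full reflectance spectrum per pixel,
and the two tissue types differ spectrally through their water content
(absorption peaking near 980 nm), adipose content (near 740 nm) and
hemoglobin oxygenation (500–600 nm double-band structure).  This package
implements a per-pixel classifier over HSI hypercubes: every annotated
pixel is represented by the 5 × 5 × 100 sub-volume centered on it, and a
compact spectral–spatial CNN maps that sub-volume to one of the two tissue
classes, producing a tissue prediction map.

## Data model and preprocessing

A hypercube is an H × W × B array of relative reflectance (no white
balance; values are unitless and non-negative) with a strictly increasing
wavelength vector.  The emulated camera delivers 501 bands at 1 nm from
500–1000 nm; 5× spectral binning averages disjoint groups of five bands
into 100 bins.  The binning convention reconciles the nominal 500–995 nm
grid with the trailing bands: bin *i* is the arithmetic mean of bands
500+5*i* … 504+5*i* nm, so bin 99 covers 995–999 nm and the 1000 nm band
is dropped.  Bin wavelengths are reported as bin-start values
(500, 505, …, 995).  Arithmetic-mean aggregation preserves the reflectance
scale; the convention is asserted by a worked example (a spectrum whose
band *k* equals *k* bins to 2, 7, …, 497).

Annotation masks use three labels — 0 unlabeled, 1 colon-mesocolon
(resect), 2 retroperitoneum (preserve) — stored as lossless PNG with the
exact palette green (0, 255, 0) / purple (128, 0, 128), configurable via
YAML.  Cubes travel in single-file HDF5 containers with named datasets
(`reflectance`, `wavelengths_nm`) and an `animal_id` attribute; readers
fail loudly, naming the missing field or the mismatched shape.

## Patch extraction and class balance

One training sample is extracted per annotated pixel whose full 5 × 5
window fits inside the image (margin 2).  Border-adjacent annotated pixels
are excluded rather than padded — no padding policy is documented for the
original pipeline, annotated regions sit in the image interior, and
exclusion keeps every sub-volume physically real.  The excluded count is
logged so the accounting is auditable.  Extraction order is row-major and
deterministic; shuffling happens only inside training, seeded.

Class imbalance (≈4.3:1 colon-mesocolon : retroperitoneum) is handled by
inverse median frequency weighting: w_c = median(f)/f_c with f_c the class
frequency in the *training split only*.  For two classes the median of two
frequencies is their midpoint, so w_c · f_c = 1/2 for both classes — the
normalization identity the tests assert.  Equal frequencies give weights
(1, 1); the minority class always receives the larger weight.

## Architecture

The CNN (31,532 trainable parameters, seven trainable layers) is:

| layer | kind                         | out ch | params |
|-------|------------------------------|--------|--------|
| Conv1 | 3×3×3 spectral–spatial conv  | 20     | 560    |
| Pool1 | spectral conv k=3, stride 2  | 20     | 1220   |
| Conv2 | 3×3×3 spectral–spatial conv  | 35     | 18,935 |
| Pool2 | spectral conv k=3, stride 2  | 35     | 3710   |
| Conv3 | spectral conv k=3, stride 1  | 35     | 3710   |
| Pool3 | spectral conv k=2, stride 2  | 35     | 2485   |
| FC    | 455 → 2                      | 2      | 912    |

ReLU follows Conv1, Conv2, Conv3 and Pool3 (not Pool1/Pool2), per the
published row order.  "Pooling" layers are trainable strided 1-D
convolutions along the spectral axis, shared across spatial positions.

Padding is not documented but is over-determined by the FC input size:
spatial convolutions are unpadded (5 → 3 → 1) and the spectral chain must
run 100 → 50 → 25 → 13.  Two conventions achieve this; we use spectrally
same-padded convolutions with pool padding 1 and floor division (the
common ecosystem default).  The constructor asserts the 455-feature FC
input, so any drift fails at build time.  Parameter counts are independent
of the padding convention (they depend only on weight shapes).

The final scores are a softmax over the two FC outputs; the binary
cross-entropy of the original description is the equivalent 2-class
cross-entropy on a 2-neuron head.  Prediction ties at score 0.5 resolve to
class 1 (colon-mesocolon) — arbitrary but fixed and documented.

### NumPy implementation notes

The network, backpropagation and the optimizer are implemented directly on
NumPy (the architecture is small enough that a deep-learning framework is
unnecessary).  Activations use a channels-last layout and every
convolution is lowered to one sgemm: inputs are gathered per spectral tap
and multiplied against an expanded weight matrix whose entries are zero
where a spatial shift falls outside the kernel.  The first layer skips its
input-gradient computation.  Inside each SGD step the gradient is
accumulated over fixed micro-batches of 64 samples, which keeps the
working set cache-resident (about 5× faster than whole-batch passes on a
single CPU) while computing the exact minibatch gradient.  All arithmetic
is float32; two runs with the same configuration and seed are
bit-identical.  Forward results are independent of inference batch size up
to float32 summation-order effects (≤1e-6), and the class map is invariant.

## Training protocol

Published settings: plain batch gradient descent ("batch gradient
descent" is read as minibatch SGD without momentum, since the batch size
8192 is far below the 439,466 samples), 250 epochs, learning rate 0.01,
weight decay 0.0005, loss weighted by inverse median frequency.  Weight
decay is the classic coupled L2 term added to every parameter's gradient.
Momentum exists as a config option but defaults to 0.  No early stopping
and no inner validation split: the protocol trains a fixed number of
epochs.  Minibatches are drawn by seeded shuffling each epoch and the last
incomplete minibatch is kept (immaterial statistically, required for
determinism).

Cross-validation is grouped at the animal level: the 20 images (one per
animal) are randomly partitioned into 5 folds of 4; each fold's model
trains on the 16 out-of-fold images and predicts every annotated in-bounds
pixel of the 4 held-out images.  Class weights are recomputed per fold
from training data only.  A leakage audit records the train ∩ test animal
intersection for every fold and the run asserts it empty.

**Desk-scale profile.**  The default profile used by the analysis scripts,
tests and acceptance run is 25 epochs at batch 1024 on 160 × 120 images —
a full 5-fold CV completes in ~3 minutes on one CPU.  The full-scale
profile (250 epochs, batch 8192, 640 × 476 images) is available through
`TrainConfig`/`CohortConfig`; nothing in the code depends on the profile.

## Synthetic cohort

No public dataset accompanies the original study, so the package ships a
generator that emulates the documented structure of the data and makes the
whole pipeline testable end-to-end.

*Spectra.*  Reflectance follows a Beer–Lambert-shaped mixing model:
R(λ) = S(λ) · exp(−Σ_a c_a A_a(λ)) + ε, clipped at zero, with S(λ) a
slowly decaying power-law scattering baseline and four absorbers: water
(Gaussian centered at 980 nm), lipid (740 nm), oxyhemoglobin (double band
at 542/577 nm) and deoxyhemoglobin (broad 556 nm band plus a weak 760 nm
bump).  The curves are parametric stand-ins, not literature extinction
coefficients: only the peak locations and qualitative shapes are pinned by
the physiology, and those are what the invariants test.  Class contrast
enters through the absorber concentrations: colon-mesocolon is
lipid-richer and better oxygenated, retroperitoneum is water-richer; a
single `separation` dial scales the concentration difference, so
`separation=0` makes the class models identical (a chance-level task) and
the default `separation=1` is separable even for a nearest-class-mean
classifier (>95% pixel accuracy — the calibration test).  Per-animal
variability is an additive concentration offset shared by both classes
within an animal (SD 0.05), plus per-pixel concentration jitter (SD 0.03)
and additive reflectance noise (SD 0.01).  Unlabeled pixels get the
mixed-class spectrum with doubled jitter and tripled noise, standing in
for the ascites/vessel regions surgeons left unannotated.

*Scenes.*  Each animal's mask holds one large elliptical colon-mesocolon
region and one thin retroperitoneal strip (default thickness 6 px), area
ratio targeted at 4.3:1 (the generator targets a configurable ratio; the
published text and its own pixel counts differ slightly, 4.32 vs 4.38).
Geometry is jittered per animal; annotated regions stay clear of the
2-pixel patch margin.  Determinism: one master seed; per-animal streams
derive from hashing (seed, animal_index).

*Problem size.*  Desk-scale images are 160 × 120 with ≈200 annotated
pixels per image (≈4,000 sub-volumes per cohort) — about a 100× reduction
from the real dataset's 439,466 — chosen so that a full 5-fold CV run, and
the repeated-seed robustness checks built on it, complete in minutes on a
single CPU.  The labeled fraction (~1%) is below the real data's ~7%;
region shapes, imbalance and thin-strip structure are preserved.

*What passing tests do and do not show.*  The synthetic cohort has no
specular highlights, motion, ventilation artifacts, smile/keystone
distortion or annotation noise, and its class contrast is generative by
construction.  End-to-end recovery on it demonstrates that the pipeline —
binning, extraction, weighting, the CNN, grouped CV, metrics — is wired
correctly and can learn a separable spectral–spatial signal without
leakage; it says nothing about classification accuracy on real surgical
scenes.

## Evaluation

Metrics are computed per image over annotated, evaluated pixels only:
sensitivity, specificity, F1, MCC from the confusion table, and a
Mann–Whitney ROC AUC (ties counted ½) from the class-1 softmax score.
Cohort numbers are macro-averaged at image level: unweighted mean ± SD
(population SD, divide by n; sample SD is a flag) across images.  A metric
with a zero denominator — e.g. specificity on an image containing a single
class — is reported as NaN, excluded from that metric's average, and the
exclusion is counted in the report.  Two-class identities are asserted
rather than assumed: sensitivity(class 1) = specificity(class 2) exactly,
MCC is class-symmetric, and the AUC computed from either class's softmax
score is identical.  Error maps flag every misclassified pixel of the
evaluated support; prediction and error maps are rendered as PNG alongside
CSV per-image counts.

## Known limitations

- The spectral binning convention for the trailing bands (bin 99 covering
  995–999 nm, 1000 nm dropped) is one consistent reading of an internally
  tense description; the alternative (101-band groups) is not supported.
- Whether the original sample count includes border-adjacent pixels is
  unknown; the extractor's exclusion ledger makes this package's policy
  auditable but the two may differ.
- The absorber curves are qualitative; spectra should not be compared
  against real tissue measurements.
- Full-scale training (250 × 8192 on 439k sub-volumes) is supported but
  slow on one CPU (hours, not minutes), as the implementation is pure
  NumPy by design.
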