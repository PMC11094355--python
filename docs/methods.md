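# Methods

This note documents the models, procedures and design choices behind
`seedvigor`: what each stage computes, the parameters that matter, what the
synthetic scenes do and do not emulate, and the numerical conventions used
throughout.

## Problem setting

Seed vigor in sweet corn is graded after a seven-day germination test by
embryonic shoot length: HV (> 7 cm), MV (3–7 cm), LV (1–3 cm), NV (< 1 cm);
a seed counts as germinated when its shoot exceeds 1 cm. The published bins
overlap at their endpoints, so the package fixes the convention that 3 cm
and 7 cm belong to MV and 1 cm to LV — with that choice "germinated" and
"grade ≠ NV" are the same predicate. Germination percentages are rounded
half-up to one decimal to match how such tables are printed.

The imaging side works on hypercubes: an m×n×w array over 388–1025 nm in
360 bands. Raw counts are converted to reflectance with the black/white
reference correction

    I = (I_org − I_dark) / (I_white − I_dark).

Dark and white references may be full cubes or per-band vectors; full cubes
are averaged over pixels band-wise before use (per-pixel correction would
also be defensible; averaging is the simpler estimator and is exact for the
synthetic scenes, whose reference noise is pixel-independent). Calibrated
values are not clipped; a validity report counts pixels outside [0, 1.5].

## Synthetic scenes

No public hyperspectral seed dataset accompanies this problem, so the
generator is first-class, tested code and defines the study conditions for
everything downstream.

* **Class mean curves.** Each vigor class's mean reflectance over the
  wavelength grid is a smooth ramp plus 2–3 broad Gaussian bumps (widths
  ≥ 60 nm). Amplitudes are chosen so the empirically observed orderings
  hold: the unaged HV curve is highest on average across the full range;
  among aged classes LV is highest on average over 400–750 nm and MV over
  750–1025 nm, with LV and NV deliberately close (they are the hard pair in
  practice). A seeded ±8 % jitter on bump amplitudes varies curves between
  seeds; the orderings are re-verified numerically on every call.
* **Per-seed scatter.** Each seed distorts its class curve as
  `offset + slope·curve(λ)` with `slope ~ N(1, 0.05²)` and
  `offset ~ N(0, 0.02²)`, plus band-wise Gaussian noise (default σ = 0.01,
  i.e. 1 % of the reflectance scale). This is exactly the distortion family
  MSC is built to invert, which makes MSC testable against ground truth.
* **Geometry.** The default scene is a 5×10 lattice of non-overlapping
  ellipses (semi-axes 6×4.5 px, ≈ 85 px each, ±2 px center jitter) on a
  128×256×360 cube — desk-scale rather than the 1211×960 of a real line
  scanner, preserving the geometry that matters (blob-like seeds well
  separated on a dark background, ~50 per scene).
* **References and counts.** Dark current sits at 100 counts; the white
  panel at 4000 counts with a smooth band-dependent illumination profile.
  Raw counts are constructed as `dark + ρ·(white − dark) + noise`, so
  calibration inverts the construction exactly when all noise terms are
  zero — a machine-precision oracle used by the tests.
* **Shoot lengths** are drawn uniformly within each class bin (HV capped at
  12 cm); only the bins are published, not distributions.
* **Label recovery.** The generator's round-trip invariant (render →
  calibrate → segment → mean spectrum → nearest-class-curve assignment
  recovers ≥ 95 % of labels at σ ≤ 1 %) uses an affine-invariant
  assignment: each spectrum is regressed on each class curve
  (`s ≈ a + b·curve`) and the smallest residual wins. This is the matched
  decision rule for the scatter family above; a plain Euclidean
  nearest-curve rule conflates the per-seed offset with the between-class
  gap and loses several points on the LV/NV pair.

What the scenes do **not** emulate: radiative-transfer effects, seed
morphology beyond ellipses, touching seeds, specular highlights, spectral
smile, or sensor nonlinearity. Passing tests therefore demonstrate that the
pipeline's logic is correct under controlled distortions, not that the
reported accuracies transfer to real seed images.

## Segmentation

The per-seed extraction follows the standard single-band recipe: take the
band nearest 635.77 nm (seeds show crisp outlines there), apply a 3×3
median filter and min–max rescale, threshold with Otsu's method, clean with
one 3×3 morphological opening, and label 8-connected components. Components
smaller than `min_area` (default 20 px) are dropped; survivors are numbered
row-major by centroid so seed numbering is stable. Each ROI carries its
mask, the ROI-averaged spectrum, and a 46×46 crop of the full cube centered
on the centroid (zero-padded at scene edges; larger seeds are
center-cropped). Otsu is computed over an explicit `levels`-bin histogram
(default 256) and returns the bin edge maximizing between-class variance,
ties to the lowest threshold; the tests check it against an exhaustive
split-point search and against scikit-image.

## Chemometric preprocessing

* **SNV** standardizes each spectrum to mean 0, sample SD 1 (ddof = 1).
* **MSC** regresses each spectrum on a reference (`s ≈ a + b·ref`, least
  squares) and returns `(s − a)/b`. The reference defaults to the
  training-set mean spectrum and is stored in the transformer so held-out
  data is corrected against the same reference. A fitted slope below 1e−8
  is an error (the spectrum carries no signal along the reference).
* **SPA** greedily selects bands by maximal residual column norm after
  projection onto the span of the already-selected columns (Gram–Schmidt
  update); selections are nested by construction. The default start is the
  band of largest column norm.
* **CARS** runs Monte-Carlo calibration subsets (80 % of samples), fits
  PLS-DA (one-hot PLS regression + argmax, components capped at 10), ranks
  bands by absolute coefficient weight, enforces the exponentially
  decreasing retention schedule `round(p·a·e^{−k·i})` with
  `a = (p/2)^{1/(N−1)}`, `k = ln(p/2)/(N−1)` (so run 1 keeps all p bands
  and run N keeps 2), then resamples survivors by weight (adaptive
  reweighted sampling). The run whose retained subset maximizes
  cross-validated PLS-DA accuracy wins. Fully seeded and bit-reproducible.
* **PCA reduction** treats every pixel of a 46×46×w crop as one
  w-dimensional observation, fits PCA on the pooled pixels of the training
  crops only (subsampled to 100k pixels for large pools), and projects all
  crops to 46×46×k (default k = 5). Fitting on training crops only avoids
  leakage into the test split.
* **Band significance** masks use a per-band two-sample Welch t-test;
  `True` marks bands where two classes do *not* differ at the given alpha
  (default 0.01) — the shaded regions when comparing aged-class mean
  spectra. Welch is chosen because per-band variances differ between
  classes and no specific test is canonical here.

Preprocessing order is configurable; the default pipeline applies scatter
correction before band selection.

## Classifiers

* **SVM**: RBF kernel, exhaustive grid over c, g ∈ {2⁻⁸ … 2⁸} (17×17 = 289
  pairs at exponent step 1, step configurable), scored by stratified CV
  accuracy; ties break to smaller c then smaller g; one-vs-one multiclass
  (the library default, made explicit).
* **ELM**: hidden weights and biases drawn once from U(−1, 1), never
  trained; `β = pinv(H)·one_hot(y)` in a single least-squares solve.
  Activation defaults to sigmoid (tanh/ReLU available); hidden size is
  picked by a validation sweep over {50, 100, 200, 500} when not given.
  With at least as many hidden units as distinct samples, H has full row
  rank and the model interpolates arbitrary labels — an exactness oracle in
  the tests.
* **Networks**: five architectures built on an in-package numpy layer
  library (valid-padding conv 2-D/1-D via im2col, max pooling, LSTM with
  forget-bias 1, batch norm, dropout, dense; hand-written backprop verified
  against finite differences; SGD-with-momentum-0.9 and Adam; softmax
  cross-entropy loss). Image tensors enter LSTMs rows-as-timesteps: the row
  index is the timestep and the flattened (width × channels) row is the
  feature vector.

  | name | layer stack |
  |---|---|
  | cnn2d | conv5×5(6) → pool2×2 → conv5×5(16) → pool2×2 → FC 120 ReLU → FC n |
  | cnn1d | conv1×3(8) → pool1×2 → conv1×3(16) → pool1×2 → drop .2 → FC 128 ReLU → drop .2 → FC n |
  | lstm1d | drop .2 → LSTM 64 → drop .2 → FC 64 ReLU → FC n |
  | lstm_image | 3×LSTM 64 → BN → FC 64 ELU → FC n |
  | cnn_lstm | conv3×3(8) → conv3×3(16) → 2×LSTM 64 → BN → FC 128 ELU → FC n |

  The class head defaults to n = 4 (HV/MV/LV/NV). Descriptions of this
  model family sometimes put 5 neurons in the final layer despite four
  classes; the head is parameterized and defaults to the class count. LSTM
  "blocks" are single 64-unit layers (no published unit counts exist);
  convolution filter counts for the 1-D and hybrid models are likewise
  unpublished and set to 8/16. Convolutions in the declared stacks carry no
  explicit activation — max pooling and the LSTM gates supply the
  nonlinearity — and every model ends in a softmax head. Training runs a
  fixed epoch budget (default 100, after which test accuracy plateaus on
  both synthetic and published curves); early stopping is off by default.

## Firefly optimizer

The firefly algorithm moves candidate x_i toward every brighter x_j:

    x_i ← x_i + β₀·e^(−γ·r²)·(x_j − x_i) + α·(u − ½),   u ~ U[0,1] per dim

with r the Euclidean distance. Brightness ranking is frozen at the start of
each iteration while positions update in place; the brightest firefly takes
a pure α-random step (it has no attractor); positions are clamped to the
box and integer dimensions rounded after every move; α is constant over
iterations (no annealing). Defaults α = 0.2, β₀ = 1, γ = 1, NP = 10,
T = 20 — standard values, all configurable.

The (lr, bs) tuner searches a 2-D box — lr ∈ [1e−4, 1e−1] on a log10
scale, bs ∈ {1,…,32} — **normalized to the unit square** for the search
itself: with raw coordinates the bs axis spans 31 units, so γ·r² kills all
attraction and the α-step cannot cross integer boundaries; on the unit box
both dimensions move on comparable scales. Candidates are decoded back to
(lr, bs) for every evaluation. The objective is the validation
misclassification rate `1 − (agreements/samples)` from a trainer callback
that uses a fixed inner 7:3 train/validation split and a reduced epoch
budget (default 10) so each firefly evaluation stays cheap; the final model
is retrained at the optimum on the full training set. The incumbent default
(lr, bs) can be planted in the initial population, which guarantees the
tuned objective never exceeds the default's. Repeated candidates are served
from a cache rather than retrained.

## Evaluation

`stratified_split` implements a per-class 7:3 split whose train side totals
exactly `floor(0.7·n)`: per-class floors first, then leftover seats by
largest fractional remainder (for class counts 125/120/127/124 this gives
347 train / 149 test). Accuracy is reported to 2 decimals; confusion
matrices are true × predicted counts. One top-level seed fans out to
per-stage seeds via `numpy.random.SeedSequence`, so an experiment is
reproducible bit-for-bit on CPU from a single integer.

## Problem sizes and defaults used by the shipped experiments

The end-to-end experiment simulates 4 scenes (200 seeds) at σ = 0.01,
trains the CNN-LSTM for 100 epochs (Adam, lr 0.002, batch 8) on the 70 %
split of PCA-reduced 46×46×5 crops (inputs scaled by the training-pool SD)
and evaluates on the remaining 30 %. The firefly tuning demo uses 5
fireflies for 5 iterations with a 10-epoch inner budget on a 2-scene
dataset. These sizes keep a full run at minutes on one CPU while leaving
every stage of the method intact.

## Known limitations

* The synthetic scenes are far easier than real seed images (no touching
  seeds, no morphological variation, Gaussian noise only); accuracies
  obtained here are upper bounds of pipeline correctness, not field
  performance claims.
* VISSA band selection is not implemented (no published algorithm to
  follow); the selection interface accepts additional selectors.
* The network library is CPU/float64 and deliberately small; it is not a
  general deep-learning framework and has no GPU path.
* CARS results depend on the Monte-Carlo seed by design; only the seeded
  run is reproducible.
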