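# Methods

This note records the models, parameter choices and numerical conventions
behind `plateworm`, and what the synthetic experiments do and do not
demonstrate.

## Detection model

The detector is a classical sliding-window pipeline. A plate image is
preprocessed globally, tiled into square windows, and each window is
classified independently; every positive window becomes one detection.
There is no non-maximum suppression by default (a worm straddling several
windows is framed several times, which is the desired visualization for
manual review); `merge_detections` offers a greedy union for counting
use-cases.

### Preprocessing

Backlit imaging makes worms dark on a bright field, so all signal is in
edges. The chain is fixed:

1. grayscale (BT.601 luma for RGB input);
2. Gaussian blur, default 5×5 — large enough to suppress hairline
   scratches (1–3 px), small enough to keep worm-boundary edges
   (body width 6–12 px). The kernel width follows the conventional
   auto rule `sigma = 0.3·((k−1)/2 − 1) + 0.8` unless set explicitly;
3. adaptive binarization against a Gaussian-weighted local mean
   (`block_size = 101`, offset `c = 3`, output {0, 255}); per-pixel
   thresholds make the result invariant to smooth illumination
   gradients, which flat thresholding is not;
4. Sobel derivatives of kernel size 1, i.e. the pure central difference
   `[-1, 0, 1]` in x and y, no smoothing row.

Borders are reflected everywhere so the image frame itself generates no
edges. A bypass flag (`enabled: false`) skips step 3 and differentiates
the blurred grayscale directly — the "no preprocessing" ablation; the
gradient source then changes accordingly, which is the natural reading of
that ablation since the Sobel step is the gradient source by definition.

Binarizing before differentiation quantizes gradients to a small lattice
(components in {0, ±255, ±510}); the HOG below is designed for that
regime.

### HOG on the binary edge map

Cells are 8×8 px; each pixel votes its full gradient magnitude into
exactly one of 9 unsigned orientation bins (20° each, 0–180°). Hard
assignment — no bilinear bin or cell interpolation — is deliberate:
on a binarized map orientations already sit on a coarse lattice, and
vote-splitting would only blur the few attainable angles. (A
`soft_binning` flag and an unweighted counting mode exist for
comparison.) Blocks of 2×2 cells, stepping one cell (50% block overlap),
are L2-normalized as `v / sqrt(‖v‖² + ε²)` with `ε = 1e−6` — the simplest
scheme that leaves all-zero blocks at zero; there is no clipping
(L2-Hys). A 168-px window gives 21×21 cells → 20×20 blocks → 14 400
features. The orientation is the full-quadrant arctangent folded into
[0°, 180°), which is total (defined at `g_x = 0`) and makes the
descriptor equivariant under 180° rotation.

### Classifier

A soft-margin SVM with the histogram intersection kernel
`K(x, y) = Σ min(xᵢ, yᵢ)` — positive semidefinite on nonnegative
features, cheap to evaluate, and well matched to histogram descriptors.
The penalty is `C = 12.5`; an RBF kernel (`gamma = 0.5`) is retained as a
configuration option, its gamma inert under the intersection kernel. The
dual problem is solved on a precomputed Gram matrix (scikit-learn/libsvm
backend); the trained state is stored explicitly as support vectors,
signed dual coefficients and bias, so decision values are always the
transparent expansion `f(z) = Σ aᵢ K(sᵢ, z) + b`. `f = 0` maps to the
negative class: on a plate the cheaper error is a missed frame, not a
spurious one. Ten-fold stratified cross-validation is provided for error
estimation only; no hyperparameter search is performed.

Models persist to a single archive (JSON header + raw float64 arrays)
whose bytes are a pure function of the model — reruns from one seed are
byte-identical. The archive embeds a fingerprint of the preprocessing and
HOG configuration; prediction with a mismatched pipeline is refused.

### Window tiling

Stride is `round(window · (1 − overlap))`; windows that would overhang
the image are dropped, not padded (a 3024×4032 capture therefore tiles
into exactly 18×24 = 432 nonoverlapping windows, with no uncovered margin
at either 0% or 50% overlap). Window sizes not divisible by the 8-px cell
(42, 67, 126 in the benchmark sweep) truncate the trailing pixels of the
cell grid, with a logged warning.

## Synthetic scenes

The generator emulates the imaging conditions the detector targets, at
the scale implied by the window-size reasoning: an adult worm (~1 mm)
spans ~100 px, roughly a 168-px window diagonal. Nothing in the pixel
size is measured — it is an inference, and configurable.

- **Worm bodies**: bounded-curvature random walks at 1-px steps whose
  curvature varies sinusoidally along the body (amplitude 0.02–0.06
  rad/px, wavelength 0.6–1.4 body lengths), giving the characteristic
  undulating silhouette without simulating locomotion. Width tapers as
  `w_max · sin(π·s/L)` — maximal at midbody, vanishing at head and tail.
  Default length 70–120 px, width 6–12 px; slenderness
  (`length ≥ 3 · width`) and backlit contrast
  (`worm darker than background`) are enforced invariants.
- **Plate**: bright background (200), mild linear illumination gradient
  (±7.5 gray levels), dark dish-rim ring, additive Gaussian sensor noise
  (σ = 6), clipped and quantized to 8 bits.
- **Distractors** (rendered, never annotated): hairline scratches
  (1–3 px chords), marker-pen inscription strokes (20–50 px wide — a
  felt-tip line is ~0.5 mm, far wider than a worm), and solid right-angle
  tape wedges at the image edge. These are the false-positive classes
  observed on real dishes.
- **Labeled crops**: positives render one worm and crop around its
  bounding-box center with ±20 px uniform jitter (hand-selected squares
  are not pixel-centered); negatives come from worm-free scenes, 30% of
  them centered on a distractor, the rest sampled inside the dish.
  Negative mini-scenes vary in extent so the rim crosses crops at a
  range of curvatures. Each crop records its own seed; identical configs
  reproduce bit-identical sets.

### What the generator does not model

Agar and bacterial-lawn texture, optical blur and vignetting beyond a
linear gradient, larval stages, overlapping or clumped worms, and
condensation. Passing the synthetic experiments therefore shows that the
pipeline separates slender curved dark bodies from its named distractor
classes under noise and illumination drift — not that it reaches the same
numbers on any particular real dataset. Conversely the synthetic task is
not trivial: 30% of negatives carry a distractor, and binarization turns
sensor noise into speckle edges everywhere, so negative feature vectors
are dense, not empty.

## Reference experiment and problem sizes

`run_crop_experiment(seed)` generates 600 positive / 600 negative crops
(train and test streams seeded independently), trains on 500/500 and
scores 100/100 held out. With the frozen defaults this reaches
sensitivity 0.92–0.97 and specificity 0.90–0.95 across seeds (0.95/0.94
at seed 1), computed in a few minutes on one CPU. The test suite runs the
same experiment once at seed 0 and reuses it; plate-level tests use
504–1008 px plates with 0–13 worms, and unit oracles run on ≤64×64
images.

## Known limitations

- **Windowing misses.** At the default 50% overlap a worm can lie up to
  42 px off the nearest window center; such worms are sometimes
  classified negative in every window that touches them. On 13-worm test
  plates, 8–11 of 13 worms are typically framed at 50% overlap and all
  13 at 75% overlap (at ~4× the window count). This mirrors the known
  behavior of the window/overlap configuration this detector family
  uses; denser overlap or jittered ensembles are the standard remedies.
- **Statistic conventions.** The false-positive ratio is reported as
  `fp / (tp + fn)` — against the positive total, *not* `1 − specificity`
  — preserving the reference table's printed formula; a debug-level note
  is logged when it is computed. Display values truncate (not round) at
  three decimals, again matching the reference table's convention.
- **Pairwise similarity test.** The positive–negative pair statistic is
  an independent two-sample t-test over vector elements (pluggable);
  NaN p-values (zero-variance degenerate pairs, e.g. an edge-free
  negative) are recorded as 0 by convention before averaging.
- The SVM is binary and uncalibrated; no probability estimates, no
  multi-scale pyramid, no tracking.
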