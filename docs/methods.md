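# Methods

## The problem and the model family

Retinal vessel segmentation assigns each pixel of a fundus photograph to
vessel or background inside the circular field of view (FOV).  `fundusnet`
implements a *family* of small encoder–decoder networks (U-Nets) built from
a declarative `ArchitectureSpec`, so that the contribution of each
architectural ingredient — depth, width, convolutions per block, skip
connections, nonlinearity, and popular add-on blocks — can be varied one
factor at a time while everything else in the pipeline stays fixed.

A family member has `L` resolution levels; the filter count at level `l` is
`F0 * 2^(l-1)` (doubling after each 2×2 max-pooling, halving after each
up-sampling).  Each block is `C` consecutive 3×3 convolutions, each followed
by ReLU and batch normalization; batch normalization is applied after all
but the network's last activation.  Up-sampling is nearest-neighbour
up-pooling followed by a 1×1 channel-halving convolution.  Skip connections
concatenate encoder activations onto the matching decoder block input.  A
3×3 convolution to two channels and a softmax produce the output map.  The
default member is `(L=3, F0=16, C=2, skips, ReLU, batch norm)`.

Variant blocks: *residual* (two extra convolutions with an additive
shortcut from the first convolution's activations to the third's),
*dense encoder* (every layer's activations concatenated to all later layers,
with a 1×1 transition restoring the level width), *dilated bottleneck*
(holes in the bottleneck kernels; default rate 2, configurable — the rate
is not specified by the experiment tables, which only require that dilation
adds no weights), and *side outputs* (per-decoder-level 1×1 projections,
bilinearly upsampled to input shape and supervised with an auxiliary
mean-square error).

## Parameter-counting convention

`kernel_weight_count` counts convolution kernel elements only.
Convolutions carry no biases (the batch-norm shift supplies the offset) and
normalization scale/shift parameters are excluded; they are reported
separately as `total_trainable_count`.  This convention — together with
the 1×1 up-projection and a bias-free 3×3 two-channel head — reproduces
nine independent published counts exactly (108,976; 27,352; 6,892; 1,750;
451; 23,984; 49,072; 97,456; 109,072), so the built networks are bias-free
by construction.  The count is an exact quadratic in the initial width,
`A·F0² + B·F0`, with `A = 424`, `B = 27` for the default topology.

Four published counts are *not* reproducible under this convention
(one-level 17,344; five-level 1,852,336; residual 154,768; dense
2,501,067): the one-level layer chain, the residual insertion widths and
the dense growth rate are not specified precisely enough to pin a unique
reading.  `reproduce-counts` emits these rows flagged "not asserted";
counting residual/dense specs raises `UnsupportedCountingError`.

## The NumPy network engine

The networks are implemented directly on NumPy arrays (`fundusnet.nn`):
3×3/1×1 convolutions via nine shifted batched matrix products, batch
normalization with running inference statistics, 2×2 max-pooling,
nearest-neighbour up-pooling, separable bilinear resizing, channel softmax,
and Adam.  Back-propagation is hand-written per layer and executed in exact
reverse topological order by the model.  All analytic gradients are checked
against float64 central finite differences in the test suite (relative
agreement ~1e-7 across every block variant).  The models in this family are
small (hundreds to ~10⁵ weights), so CPU matrix products are entirely
adequate for the desk-scale experiments the package targets.

## Preprocessing

Raw 8-bit RGB fundus images pass through five stages: (1) green channel
(best vessel contrast); (2) CLAHE with an 8×8-pixel window and max slope
3.0 — scikit-image's `equalize_adapthist` expresses the clip as a fraction
of the tile pixel count, so max slope `S` over 256 bins maps to
`clip_limit = S/256`; (3) min–max normalization to [0, 1] *within the FOV*;
(4) gamma transform `v^0.8`; (5) linear mapping of FOV values to [−1, 1].
Pixels outside the FOV take the background fill −1; a degenerate (constant)
FOV maps to 0 there.  CLAHE runs on the full frame; whether the original
protocol restricted its histograms to the FOV is unknown, and no asserted
value depends on the choice.  High-resolution databases are bilinearly
down-sampled before inference (HRF ÷4, CHASE_DB1 ÷2) and predictions
up-scaled back before evaluation.  FOV masks are eroded by four pixels
(3×3 element, four iterations — a Chebyshev margin; the protocol states
only "four pixels") for all metric computations.

## Supervision

Per-pixel loss weights emphasize thin vessels:
`W(x) = 1` on background and `max(1, 1/(0.18·d_x))` on vessels, where
`d_x` is the vessel diameter at pixel `x`.  Diameters are estimated as
twice the Euclidean distance-transform value at the pixel's nearest
medial-axis point, so edge pixels of a thick vessel inherit the vessel's
caliber instead of their own small boundary distance.  Skeleton radii are
averaged over a 5×5 window along the skeleton before propagation; raw
per-pixel EDT values carry ±0.5 px grid-quantization noise, and the
smoothing brings caliber recovery on phantoms to ~0.6 px mean absolute
error without affecting the isolated-pixel convention (diameter 2).

The objective is `L = (1/N)·Σ focal(x_i)·W(x_i) + λ·L_ℓ2` with a
class-balanced focal term (`−α(1−p)^γ log p` on vessels,
`−(1−α)(1−p)^γ log p` on background; `γ = 2`, `α = 0.9`), a probability
floor of 1e−7 inside the logarithm, and an ℓ2 penalty over convolution
kernels with `λ = 0.2`.  The penalty's normalization is exposed as
`l2_mode`: the training default is `mean` (½·mean w²), because at λ = 0.2 a
sum-type penalty dominates the pixel loss under Adam for any non-trivial
model and collapses the kernels; `sum` (½·Σ w²) is available.  Side-output
variants add one mean-square-error term per decoder tap against the one-hot
label map.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999) on randomly positioned, fully-inside patches
(DRIVE/STARE 50×168², HRF 15×400², CHASE_DB1 40×200² per minibatch), with
augmentation per patch: rotation within ±20°, shear within ±30%, zoom
50–150%, additive Gaussian noise (σ = 2% of the intensity range; the
magnitude is not specified by the protocol), and a uniform intensity shift
within ±8% of the range.  Labels and weights warp with nearest-neighbour
interpolation (labels stay binary); out-of-bounds image regions take the
background fill −1.  The learning rate decays by 10% every 10,000
iterations from a size-dependent initial value (1e−3 up to 2×10⁵ kernels,
5e−4 up to 5×10⁶, 1e−4 above — the protocol states only "the more weights,
the smaller the rate").  Validation loss is checked every 500 iterations by
default; training stops after 10 checks without improvement or at the
iteration budget, and the best-validation state is the checkpoint.  Each
configuration is repeated with distinct derived seeds (five in the full
protocol).  A seeded uniform random-search harness over user-declared
ranges is provided; the original nine-dimensional search space is not
reconstructable and is therefore not hard-coded.

## Evaluation

The binarization threshold maximizes the mean per-image F1 over the
validation images, searched exhaustively on a 256-point uniform grid (ties
toward the smaller threshold).  Per test image, inside the four-pixel-eroded
FOV: AUC on the unbinarized foreground probabilities (ties count ½ —
verified against an exhaustive pairwise-ranking oracle), sensitivity,
specificity, F1 and accuracy at the selected threshold.  An image with
neither predicted nor true foreground takes F1 = 1 (degenerate guard).
Aggregation is two-stage: per image, mean and sample standard deviation
over the training repetitions; both are then averaged over test images.
AUC is computed per image and averaged, not pooled (a pooled mode exists but
is off).  Transfer evaluation applies a trained model to another database
without retraining, carrying the source threshold (AUC, the headline
transfer metric, is threshold-free, so the carried threshold is inert for
it).

## Split schemes

DRIVE: the sorted first half of the images is the fixed test set; four of
the remaining twenty training images move to validation by a seeded draw
(the published protocol does not name them).  STARE (20), HRF (45) and
CHASE_DB1 (28): a seeded permutation is cut into four test partitions that
are disjoint across folds and jointly cover every image; the remainder
splits into validation (4, 7, 4 images respectively) and training.  The published HRF protocol
describes more training, validation and test images than the database's 45
can supply disjointly; as with DRIVE, validation is read as separated
*from* the training images, giving 26–27 training / 7 validation / 11–12
test per fold.  The training-set
reduction experiment truncates the training list to a seeded subset,
leaving validation and test untouched.

## Synthetic phantoms

The generator emulates the properties the pipeline actually consumes: a
circular FOV (radius 0.46 of the image side) on a near-black surround; a
branching vessel tree from seven rim roots performing random walks with
per-step heading noise 0.18 rad, calibers tapering asymptotically from up
to 9 px toward 1.5 px, branch probability 0.10 per step (calibrated once so
the vessel fraction of the FOV spans ~0.07–0.15, mean ~0.11, over a 50-seed
survey; the frozen test bounds are [0.05, 0.20]); vessels stamped as discs
along the polylines, with the stamp radius `cal/2 − 0.3` calibrated so the
rendered band's medial-axis diameter matches the nominal caliber on the
pixel grid.  The stored diameter map holds the stamped caliber exactly
(larger vessels win at crossings).  Rendering: radially falling illumination
(amplitude 0.30), channel bases (R 185, G 150, B 45), vessels darkening the
green channel by 35% (red 17.5%, blue 10.5%), Gaussian noise σ = 8 on the
8-bit scale.  Preset B (transfer target) differs in illumination fall-off
(0.45), vessel contrast (0.25) and noise (10).

What phantoms do *not* emulate: pathologies, exudates/hemorrhages, texture,
optic disc, inter-image color variation, annotation noise.  Two
consequences matter for interpreting the tests.  First, passing the
learnability benchmark (held-out AUC ≥ 0.95 after 2000 iterations on 8
phantoms) shows the pipeline trains and generalizes end to end, not that it
reaches published real-data scores.  Second, phantom vessels are dark tubes
on a smooth bright background — a task that is very nearly linearly
separable after preprocessing.  On such data the linear (no-ReLU) variant
converges faster than the ReLU default and reaches at least comparable AUC,
so the real-data ordering "default above linear" does **not** transfer to
the phantom benchmark; the package reports this honestly rather than
adjusting the benchmark (see the ordering test).  The 1-filter variant also
behaves worse on phantoms than its published real-data scores suggest:
with bias-free convolutions a single first-level filter can die (ReLU
inactive over the whole FOV interior), which is a real property of this
family at width 1.

## Benchmark problem sizes

The synthetic benchmark uses 12 phantoms at 512² (8 training, 2 validation,
2 held-out test).  Learnability trains the 4-filter default topology (6,892
kernels) for 2000 iterations on 96-px patches (batch 8).  The
variant-ordering comparison (default vs 1-filter vs linear, 3 seeds each)
uses 1000 iterations on 64-px patches (batch 6), which is near convergence
for this task (AUC gains from 1000 to 2000 iterations were below 0.02 for
all variants when the protocol was fixed).  The transfer check reuses the
learnability model on four preset-B phantoms and compares against a
random-weight network.

## Numerical choices and degenerate inputs

Probability floor 1e−7 in the focal logarithm; BN ε = 1e−5, running-stat
momentum 0.9; He-normal seeded initialization; max-pool ties resolve to the
first maximum; threshold-selection ties to the smaller grid point;
degenerate FOV ranges map to 0; empty vessel masks yield an all-ones weight
map; predictions are reflect-padded to pooling-divisible shapes and cropped
back.  All randomness flows through `numpy.random.Generator` seeds; derived
seeds stay below 2³¹.

## Known limitations

Real-database results require downloading DRIVE/STARE/HRF/CHASE_DB1 and
long training; the package ships the full protocol but its tests assert
only desk-scale synthetic properties.  Residual/dense counts are built but
not covered by the counting algebra.  Dense blocks follow a best-effort
reading of the growth rule.  GrabCut FOV extraction is replaced by a
luminance-threshold fallback.  Training is single-device, float32, CPU.
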