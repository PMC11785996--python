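# Methods

## Scope and model

`simqual` quantifies how similarity (reference) and quality (non-reference)
metrics respond to controlled degradations of 2-D MR slices. The pipeline
is: take a reference image, apply one of eleven calibrated distortions at
one of five strengths, normalize the distorted image and the reference
independently, then score the pair with reference metrics and each single
image with non-reference metrics. Long-format records are aggregated into
sensitivity tables (median per metric × distortion over all images and
strengths, pooled) and relative tables (each cell divided by the metric's
pooled all-distortion median), which expose which distortions a metric is
unusually sensitive or blind to.

All metrics operate on real-valued images. Because most classical metrics
were designed for 8-bit integers, every metric with internal constants or
thresholds takes a data-range parameter `L` (max − min over a single image,
an image pair, or a dataset; these nest: `L_I ≤ L_{I,R} ≤ L_D`). The
default for paired metrics is the joint pair range — a single-image range
would make the score depend on which image is called the reference.

## Normalizations

Six methods: minmax (affine onto `[j1, j2]`), cminmax (percentile clipping
at `p = 5%` before minmax), zscore (population standard deviation —
deterministic, no `n−1` ambiguity), quantile (median 0, IQR 1), binning
(`B = 256` equidistant bins, index `floor((x − min)/(max − min)·B)` with the
maximum pinned to `B−1`), and piecewise-linear histogram standardization
(two affine pieces matching a low percentile, the foreground histogram
mode, and a high percentile to landmarks fitted on training images;
defaults 1st/99th percentile, mode from a 256-bin histogram of nonzero
pixels because skull-stripped slices have an exactly-zero background that
would otherwise dominate). Background zeros are included in all other
statistics, since normalizations are applied to whole slices. Affine
methods store scale/shift in a record for exact inversion.

## Distortion strength schedules

Each distortion is a pure function of (image, parameters, seed); the
schedule maps strength 1–5 to parameters, strictly monotone in the
controlling magnitude, and is fully overridable in configuration. The
anchor is translation strength 1 = 1% of the image extent (2.4 px at
240×240). The remaining defaults were chosen once so that strength 1 is
barely visible on the default phantom and strength 5 clearly corrupts it:

| distortion | parameter | strengths 1–5 |
|---|---|---|
| translation | fraction of W/H per axis | 0.01, 0.02, 0.04, 0.08, 0.16 |
| elastic | control-grid n / σ (px) | (8, 0.5), (7, 1.0), (6, 1.25), (5, 1.6), (4, 2.0) |
| gamma high | γ | 1.2, 1.5, 2.0, 2.5, 3.0 |
| gamma low | γ | 1/1.2, 1/1.5, 0.5, 0.4, 1/3 |
| intensity shift | fraction of L_I | 0.01, 0.02, 0.05, 0.1, 0.2 |
| ghosting | line attenuation (4 ghosts) | 0.05, 0.1, 0.2, 0.35, 0.5 |
| stripes | k-space coefficient gain | 16, 64, 256, 1024, 4096 |
| bias field | exponent scale | 0.1, 0.2, 0.4, 0.7, 1.0 |
| Gaussian noise | σ as fraction of L_I | 0.005, 0.01, 0.02, 0.035, 0.05 |
| Gaussian blur | σ (px) | 0.5, 1, 2, 3, 4 |
| replace reflect | fraction of hemisphere | 0.2, 0.4, 0.6, 0.8, 1.0 |

The elastic schedule is deliberately mild: the calibration property is that
even the strongest elastic deformation degrades every reference metric less
than the weakest translation — a few strong local warps cost metrics less
than a coherent global shift. The stripe gains look large because a smooth
image's spectrum is tiny at the default off-axis frequency `(H/8, W/6)`;
the gains were chosen so that the induced stripe amplitude spans "barely
visible" to "dominating" on the default phantom. Ghosting attenuates every
4th spectral line along the phase-encode (row) axis, excluding DC and
including conjugate-symmetric partners so the output stays real. Noise σ is
a fraction of the image's own range so strengths transfer across intensity
scales. Per-grid-cell seeds are derived as a CRC of (global seed, image id,
distortion, strength): reproducible, yet varying across the grid.

## Reference metrics

SSIM uses the original 11×11 Gaussian window (σ 1.5), population
covariances, and constants `C1 = (0.01·L)², C2 = (0.03·L)², C3 = C2/2`
(the occasionally printed exponent 1 on C2 is treated as a typo for the
standard squared form). MS-SSIM evaluates the contrast-structure term at
five dyadic scales (2×2 average pooling) and luminance at the coarsest,
with the standard exponents (0.0448, 0.2856, 0.3001, 0.2363, 0.1333);
negative contrast-structure responses are clamped at zero before
exponentiation; inputs must have min(H, W) ≥ 176 so the 11-tap window is
valid at scale five. CW-SSIM computes the complex-coefficient index over a
log-Gabor bank (4 dyadic levels × 8 orientations, 7×7 sliding windows,
stabilizer `K = 1e-4·L²`). The bank starts one octave below Nyquist; the
finest octave carries mostly pixel noise and excluding it — as
steerable-pyramid implementations do by discarding the high-pass residual —
is what gives CW-SSIM its characteristic noise robustness while coefficient
magnitudes remain tolerant to translations of a few pixels.

PSNR is `10·log10(L²/MSE)`, infinite for identical images. NMSE divides
MSE by the reference variance and is intentionally asymmetric. NMI bins
each image to 256 equidistant bins over its own min–max, making it (like
PCC) invariant to positive affine rescaling of either image; both therefore
score constant intensity shifts as perfect similarity. PCC is reported on
its natural [−1, 1] scale. LPIPS/DISTS are exposed as adapter contracts
only — their value lies in pretrained weights this package does not ship —
with inputs minmax-normalized to [−1, 1] / [0, 1] and a structured error
when no backend is registered.

## Non-reference metrics

Blur Effect (scikit-image) measures gradient loss under re-blurring. The
blur-ratio/mean-blur pair classifies candidate edge pixels (across-edge
variation above `20·L/255`) by an inverse-blurriness ratio — center-vs-
neighbor-mean difference over across-edge variation, 0.5 at an ideal step,
0 on a ramp — with pixels below 0.25 counted as blurred; the construction
is scale-free, so scaling an image together with `L` leaves BR/MB
unchanged. Variance-of-Laplacian uses the 5-point 3×3 stencil. Blurred
edge widths detects vertical edges by Sobel magnitude (threshold the larger
of the rescaled 8-bit constant and 20% of the image's maximum gradient,
with row-wise non-maximum suppression) and walks to the local intensity
extrema along the row; the walk stops when a step falls below one
quantization level (`L/255`) — the tolerance implicit in 8-bit data, without
which float-valued smoothing produces arbitrarily long monotone tails.
JNB/CPBD remap the image to a rounded [0, 255] grid, pool width/just-
noticeable-width ratios (`w_jnb` = 5 px below block contrast 50, else 3 px;
β = 3.6) over 64×64 edge blocks; CPBD is the fraction of edges whose blur-
detection probability stays at or below 0.63. MLC/MSLC average Pearson
correlations over adjacent line pairs / pairs half an image apart;
exactly-constant lines (zero peak-to-peak) are skipped since correlation is
undefined there. Mean total variation is the mean `sqrt(dx² + dy²)` with
central differences and one-sided edges, so a unit ramp scores exactly 1.

## Synthetic phantom

The generator emulates the properties that matter for metric behavior in
skull-stripped, atlas-registered brain slices: 240×240 field of view,
exactly-zero background over >25% of pixels, an elliptical head with
gray/white/ventricle compartments giving a bimodal foreground histogram, a
float intensity range (default [0, 1500]) that exercises non-8-bit code
paths, light smoothing (σ 1 px) plus seeded texture noise, and an optional
three-class nested tumor (whole ⊇ core ⊇ enhancing, the enhancing core
brightest) at a randomized lateral offset in exactly one hemisphere, with
analytically derived label masks. It does not model MR physics, partial
volume, coil profiles, anatomical variability, or realistic tumor
morphology — passing tests demonstrate metric properties (invariances,
monotonicities, sensitivity orderings), not clinical performance on real
BraSyn-like data.

## Problem sizes and numerical choices

The sensitivity suite runs 20 phantoms × 11 distortions × 5 strengths ×
2 normalizations with the inexpensive metrics, plus targeted MS-/CW-SSIM
evaluations for the ordering checks; 20 images are enough for stable
medians of these strongly separated effects. Degenerate inputs are rejected
at the boundary (NaN/Inf anywhere, images below 8×8, constant images where
a metric needs spread); inside the benchmark grid a failing metric yields a
missing-value record carrying the reason instead of aborting the run.
Center slices use `floor(depth/2)`. CPBD on piecewise-constant phantoms has
a narrow discriminating range (high-contrast edges cross the
just-noticeable width quickly), so its strict blur ordering is checked on a
nearly unsmoothed phantom at small σ; DSC under hemisphere mirroring
saturates at 0 once the band covers the whole head hemisphere.

## Known limitations

Learned metrics require externally registered backends. The strength
schedules are this package's own visual calibration against the synthetic
phantom, not a reader study; absolute sensitivity-table values therefore
depend on the phantom cohort, and only orderings should be compared across
datasets. All metrics are 2-D; volumetric variants are out of scope.
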