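# Methods

## Problem and model

Above-ground biomass (AGB, kg/hm²) of potato is estimated per experimental
plot and growth period from three image-derived feature families: gray-level
co-occurrence (GLCM) texture statistics at several ground resolutions, Gabor
magnitude-image texture statistics at several kernel scales, and canopy height
from DSM differencing. Features are regressed on measured AGB with LSSVM, ELM
and PLSR; replicate block 1 is held out for validation, blocks 2–3 calibrate.

## Raster conventions

World coordinates are metres; `origin` is the world position of the centre of
pixel (0, 0) and the row index increases southward. Ground sampling distance
(GDS) is cm/pixel. Resampling from the 1 cm base image to a coarser GDS uses
the nearest-neighbour rule `src = floor((dst + 0.5) · ratio)` (pixel-centre
alignment; corner alignment is the other defensible choice and is not used).
Coarse grids are always produced in a single hop from the GDS1 image —
cascaded nearest-neighbour resampling is deliberately not equivalent and not
supported. ROI extraction keeps every pixel whose centre lies inside the plot
rectangle. DN rasters are uint8; DSM/CHM rasters are float with NaN nodata,
and all zonal statistics skip nodata.

## GLCM textures

The co-occurrence matrix counts ordered gray-level pairs at a fixed offset
(default distance 1) and is symmetrised and normalised. Eight statistics are
computed: Mea = Σ i·p(i,j); Var = Σ (i−Mea)²·p; Hom = Σ p/(1+(i−j)²);
Con = Σ (i−j)²·p; Dis = Σ |i−j|·p; Ent = −Σ p·log₂ p (bits; 0·log 0 ≡ 0);
Sec = Σ p²; Cor = Σ (i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) with Cor ≡ 1 for zero-variance
(constant-window) matrices, since a constant window is perfectly
self-similar. Gray levels: each channel is quantized to 32 levels by linear
binning of its full-image range (constant channels map to level 0); 32 levels
is standard texture practice balancing co-occurrence sparsity against
discrimination.

Per-pixel texture images use a centred moving window (default 5×5, direction
45°, i.e. offset (−1, 1)), reflect-padded at the edges so the output grid
keeps the input size. Plot-level features are ROI means of these texture
grids, with the window confined to the plot's own pixels (reflect padding at
the ROI boundary) so statistics never mix in neighbouring plots or bare
paths. The windowed engine maintains the co-occurrence histogram and every
moment incrementally as the window slides (numba inner loop); it is exact and
is tested pixel-for-pixel against an explicit per-window GLCM oracle.

Feature names follow the channel-prefix scheme: `R-GDS30-Con`, `G-S2-Ent` —
channel, source tag (ground-resolution level or Gabor scale), statistic.

## Gabor textures

Kernels follow the classic Gabor wavelet family: for scale index ν = 0..4
(tags S1..S5) the wave number is k = k_max/f^ν with k_max = π/2, f = √2 and
envelope width σ = 2π; orientations are 0°, 45°, 90°, 135° (20 kernels).
The DC term is removed using the envelope-weighted mean of the carrier over
the truncated support (analytically ≈ exp(−σ²/2)), making every kernel zero-DC
to machine precision — magnitude images are then invariant to constant
illumination offsets, one of the Gabor transform's selling points for field
imagery. Support is truncated where the envelope falls below 10⁻³ of peak.
Convolution runs in the frequency domain (reflect boundary); it equals direct
spatial convolution to ~10⁻¹³ and is tested against a nested-sum oracle.

Each magnitude image is linearly rescaled to 0..255 over its own range
(near-constant images map to 0 rather than having numerical noise stretched to
full scale), quantized, and summarised by the same windowed statistics. The
pipeline default keeps the 45° orientation (texture–AGB correlations are far
more sensitive to scale than to direction); full-bank mode retains all four
orientations, giving 8 stats × 60 magnitude images = 480 features per plot.

## Crop height

CHM = period DSM − bare-soil DSM, with negative differences clamped to 0 by
default (soil subsidence and photogrammetric noise, not canopy). Plot height
is the ROI-mean CHM in cm. The recovery diagnostic reports per-plot relative
residuals (100·|est−obs|/obs) and their RMSE.

## Feature selection and split

Pairwise correlation pruning re-implements the caret `findCorrelation`
algorithm (exact variant): repeatedly take the most-correlated remaining pair
above the cutoff (0.99) and drop the member with the larger mean absolute
correlation against all other remaining variables; ties drop the lower column
index. It is cross-checked against `caret::findCorrelation(exact = TRUE)` in
the test suite. Pruning runs per source block (per GDS level, per scale),
mirroring how selected-feature tables are organised per block in this
literature, and only on calibration rows to avoid validation leakage.
Correlations are Pearson on z-scored columns. The split is by replicate
block: repeats 2–3 calibrate (32 rows per period), repeat 1 validates (16).

## Regression models

All models z-score features by calibration statistics. Hyperparameters are
chosen by 5-fold cross-validated RMSE on the calibration set only (the study
reports no hyperparameters; log-spaced grids are standard practice):

* **LSSVM** — RBF kernel K = exp(−‖xᵢ−xⱼ‖²/σ²); solve
  [[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]. Grids γ ∈ 10⁻²..10³,
  σ² ∈ 10⁻¹..10³. Zero-variance targets short-circuit to a constant
  predictor; singular systems raise with a condition estimate.
* **ELM** — hidden layer H = sigmoid(XW + b), W and b drawn from a seeded
  uniform(−1, 1) with W scaled by 1/√d (d = feature count): without the
  scale, wide feature tables drive the sigmoid into saturation and the
  validation accuracy becomes seed-unstable. Output weights β = pinv(H)·y.
  Node grid {20, 50, 100}.
* **PLSR** — PLS1 on the standardized design (scikit-learn's NIPALS
  implementation drives the decomposition), component count cross-validated
  up to min(10, rank); requests beyond the usable rank are capped with a
  warning.

Prediction aligns features by column name and never mutates the fitted state.

## Accuracy metrics

RMSE = √(Σ(ŷ−y)²/n); MAE = Σ|ŷ−y|/n; NRMSE = 100·RMSE/mean(y) (the mean
convention — the normaliser is not uniquely standardised in this literature,
so the choice is stated); R² = 1 − SS_res/SS_tot on the evaluated split, with
squared Pearson correlation reported alongside since the two diverge for
biased predictions. Stratified NRMSE splits at 1000 kg/hm² and normalises
each stratum by its own mean; empty or degenerate strata are undefined
(None), not zero.

## Synthetic field generator

The generator emulates the study design: 48 plots (IDs s01..s48) in three
replicate bands, 32.5 m² plots (6.5 × 5.0 m) with 0.6 m row spacing at GDS
1 cm, imaged in three periods plus a bare-soil flight. The real experiment's
treatment layout (18 density + 24 nitrogen + 6 potassium plots) does not
partition into three equal replicates, so the generator uses a simplified
3 × 16 layout in which the 32/16 calibration/validation split arises exactly
— the split sizes, not the agronomy, drive the pipeline. Treatments cycle
through density/nitrogen/potassium labels that set a latent per-plot vigour,
which in turn drives canopy cover and plant height.

Canopy is rendered procedurally: leaf blobs (disks of the leaf-size
parameter, default 9 cm — potato leaves are wide) are seeded along crop rows
with a Boolean-model intensity matched to the plot's cover parameter and
nested seed sets (so rendered cover is monotone in the parameter), over a
mulched-soil background with low speckle. Canopy pixels carry stronger
per-pixel colour jitter than soil and a crown-shading profile, so canopy is
high-frequency relative to soil — the property that makes texture statistics
track cover. Per-period colour shifts (yellowing in P3) encode phenology.
A smooth multiplicative illumination field (±5%) and low-relief terrain
(amplitude 5 cm, 12 m correlation length) complete the scene. The DSM is
terrain + rendered height field + per-pixel noise (8 mm) + a smooth
per-flight artifact (5 mm).

Ground truth per plot-period: `cover_fraction` is the actually rendered green
fraction; `mean_height` is the areal (ROI-mean) canopy height of the rendered
field plus 1.5 cm observation noise (plot-sampling/ruler error); AGB follows

    agb = β₀ + β₁ · cover · mean_height · m_period + ε,
    β₀ = 150, β₁ = 50, m = (0.62, 1.00, 0.80) for P1/P2/P3, ε ~ N(0, 110²).

The paper reports only empirical correlations, so this generative model is an
invention of the package; the multiplicative cover×height term encodes that
biomass accumulates with both canopy closure and stature, the period
multiplier the assimilate partitioning cycle, and the defaults put cohort AGB
means near 300/2000/800 kg/hm² (P1/P2/P3) with the rise-then-fall pattern of
the crop. Cover saturates near 0.97 while height keeps varying — reproducing
the saturation regime that motivates adding height to texture features.

What the generator does *not* emulate: photogrammetric stitching artifacts,
weeds/shadows as separate classes, radiometric camera response, leaf-angle
effects, multi-year variation. Passing tests therefore show the pipeline's
machinery is correct and that its qualitative behaviours (texture–AGB
coupling, height fusion benefit, scale/resolution orderings) emerge under a
plausible canopy model — not that the field-data accuracies of any particular
campaign are reproduced.

## Problem sizes

The shipped analyses and the acceptance script run the texture pipeline on a
"desk-scale" variant of the design: the same 48-plot/3-period/3-replicate
layout and GDS1 base imagery, with plot footprints reduced to 3.0 × 1.8 m and
ground-resolution levels restricted to {1, 5, 10, 20, 30} cm (coarser levels
would leave fewer than 5×5 resampled pixels per plot, which the extractor
correctly refuses). The CHM recovery diagnostic runs at the full 32.5 m² plot
size. The height-fusion seed sweep uses a further-reduced variant
(2.4 × 1.2 m plots, GLCM-only at {1, 5, 10} cm) so ten full
simulate–extract–fit replicates stay cheap. These sizes are the package's
choice of desk-scale study conditions and are fixed in
`canopyagb.pipeline.desk_scale_config` / `fusion_sweep_config`.

## Known limitations and observed behaviour

* On the synthetic field the GLCM family alone is already highly informative
  (validation R² ≈ 0.97): procedural canopies carry a cleaner cover signal
  than real ones. Consequently pooling both texture families does not improve
  on GLCM-only here, unlike in field data where each family is weaker; the
  pipeline computes and reports that comparison rather than asserting a
  direction. Height fusion, by contrast, improves every texture family and is
  asserted.
* Nearest-neighbour resampling is single-hop by design; cascading hops gives
  different (and unsupported) results.
* `find_correlation`'s output can depend on column order only through
  documented tie-breaks.
* Non-rectangular ROIs, CRS reprojection and point-cloud processing are out
  of scope.
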