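# Methods

This note documents the models, parameter choices and numerical decisions
behind `corrtaste`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Coordinate and transform conventions

Pixels are 0-based with a pixel-center convention; `x` is the column, `y`
the row. A `RigidTransform` is the point map `p' = R(p − c) + c + t` about
the image center `c`; `register_rigid(ref, mov)` returns the map taking
moving-frame points into the reference frame, so the same object transforms
both the moving image (resampling, linear for intensities, nearest-neighbor
for labels so they are never blended) and point detections such as smFISH
spots. A `DeformationField` stores per-pixel displacement `u` on the fixed
grid with `warped(x) = moving(x + u(x))`; for the small smooth fixation
warps modeled here its inverse point map is obtained by fixed-point
iteration, which converges because `|∇u| ≪ 1`.

## Synthetic scenes

The generator defines the study conditions under which everything is
tested.

* **Geometry.** A circular bud (default 60 µm across at 0.5 µm/px) of
  radially oriented annular-wedge cells converging on the apical pore, with
  a constant ≥3.5 px inter-cell gap; 1–30 cells per bud. Crowded buds push
  wedges outward rather than thinning them below a segmentable width. The
  pixel size and the 1 Hz frame rate are declared defaults, chosen as
  typical for two-photon imaging at this scale, not measured values.
* **Cell classes.** sweet (Tas1R2+/R3+), umami (Tas1R1+/R3+), dual
  (Tas1R1+/R2+/R3+), sour (CA4+), silent; default mixture
  0.3/0.3/0.2/0.1/0.1.
* **Counts.** Expressed genes draw from a negative binomial (mean 25,
  dispersion 5; variance = mean + mean²/dispersion), negative genes from
  Poisson(1). Sour cells additionally enforce CA4 ≥ 14 and Tas1R ≤ 8 by
  resampling, so they always work as the negative-control population for
  receptor calling. These parameters deliberately straddle a count
  threshold in the low teens.
* **Movies.** Red (tdTomato) is static per cell; green is
  `red × g0 × (1 + ΔF/F(t))` with exponential response kinetics (rise
  τ = 2 s during the epoch, decay τ = 4 s after offset; amplitude default
  0.5). The default protocol is 20 s artificial saliva (the baseline
  window), then per tastant 20 s stimulus + 50 s washout. Per-frame rigid
  jitter and Gaussian noise are added last; injected shifts are recorded as
  ground truth. Cells live on the apical planes, nerve ROIs on the last
  (basolateral) plane.
* **Histology rounds.** Spots are isotropic Gaussians (σ = 1.5 px) at their
  true positions moved by each round's rigid truth; the nuclear channel
  attenuates by 0.8 per round; the cytosolic reporter exists only in round
  1 (quenched afterwards); bright fiducial landmark blobs persist in all
  rounds. At most 3 payload genes per round (the spectral budget); the
  default probing plan re-probes Tas1R3 in round 4 for count-stability QC.
* **Warp.** The in-vivo ↔ fixed deformation is a Gaussian-smoothed random
  field (σ = 40 px) scaled to a maximum displacement (default 2 px). Scene
  geometry lives in the fixed round-1 frame; in-vivo renderings pull images
  through the warp.
* **Nerves.** Afferent ROIs are small squares at the basolateral rim of
  their target cells. Dual-tuned nerves are generated intrinsic (adjacent
  to one dual-receptor cell) or spillover (in the gap between an
  angularly adjacent sweet/umami pair, responding to both tastants) with a
  configurable spillover fraction; the intended adjacency and attribution
  are recorded as truth.

What the generator does **not** emulate: realistic optical PSFs beyond
Gaussian spots, photobleaching, autofluorescence textures, segmentation-
resistant cell morphologies, probe aggregation in dense regions, or 3D
overlap of cells across planes. Passing tests therefore demonstrate the
correctness of the algorithms under controlled conditions, not performance
on arbitrary tissue.

## Trace analysis

Motion correction registers every frame to the temporal mean of the red
channel by subpixel cross-correlation (upsampled ×10). Plain — not
phase-normalized — cross-correlation is used because the temporal-mean
reference is motion-blurred, which biases the phase variant by several
pixels while leaving plain correlation accurate to ~0.05 px.

Traces are ROI-mean green over ROI-mean red per frame (never pixelwise, to
avoid division blowups where red is dim). ΔF/F and Z-scores are relative to
the baseline window (default the first 20 s saliva epoch; at least 5 frames;
zero baseline variance is an error, not a silent zero).

Responsiveness conjoins two printed rules — epoch Z peak above 2 baseline
SDs and epoch mean Z above 1 — both exposed as parameters; the conjunction
is the conservative reading of the two criteria, and whether the 2-SD rule
should use the peak or the mean during stimulation is genuinely ambiguous,
so both thresholds are configurable. Non-responsive epoch means are clamped
to 0, which keeps the response-index denominator positive whenever the
index is defined; the clamped values feed the index because the clamp is
defined immediately before it in the procedure. On pure-noise traces the
conjunction fires in well under 5% of seeds.

## Registration

Rigid: phase-correlation translation initialization, then Euler-2D
refinement (mean-squared-difference metric, regular-step gradient descent,
3-level multiresolution) via SimpleITK. On synthetic nuclear rounds with
rotations ≤5°, translations ≤20 px, 5% noise and 0.8 attenuation, recovery
is ≈0.02° / 0.03 px; the QC reports Pearson correlation over the Otsu
foreground of the reference (stricter than including background) and
line-profile peak offsets. Default QC profiles are anchored on the
brightest landmark in the reference (argmax comparison is meaningless on
lines crossing several equally bright nuclei); profiles are smoothed with
σ = 1 px and argmax ties break leftmost; flat profiles are flagged, not
scored.

Non-rigid: B-spline (default control-grid spacing 32 px, order 3, 3-level
multiresolution, mean-squared-difference, LBFGSB). The deformation QC is a
pairwise relative measure: for every pair of matched centroids the residual
between true and field-predicted *relative* displacement as percent of the
pair distance, RMS-aggregated in distance bins. The pairwise form makes the
metric invariant to a constant offset between the frames, and pairwise
centroid distance is the declared meaning of "measured distance". Rounds
are each registered directly to round 1, never chained, so round-to-round
errors do not accumulate.

## Spot calling

DoG bandpass (σ = 1.0/2.0 px for ~1.5 px spots) → global background
(median) subtraction → local maxima above threshold → minimum-separation
suppression (default 5 px; among maxima within the radius only the
brightest survives — the criterion is implemented as suppression, one of
two readings of a "within a radius" maxima rule) → 2D Gaussian fit with a
local background *plane* in a 7-px window for subpixel centers and
background-corrected amplitudes; a diverging fit falls back to the integer
maximum and is flagged. The "auto" threshold is median + 5 robust SDs
(1.4826 × MAD) of the background-subtracted DoG image.

Counting is digital (one spot, one molecule). Spots are first transformed
into the round-1 frame; a spot inside a label joins that cell, a background
spot within 2 px (default) of exactly one label joins it, the nearest
boundary wins among several (a deterministic stand-in for manual
dense-region curation; exact ties stay unassigned), and duplicate
detections of one molecule on adjacent planes (≤2 px lateral) collapse
transitively to the brightest. Note that dense expression *undercounts* by
construction: ~25 molecules in a few hundred px² cannot all be ≥5 px apart,
so the 5-px rule suppresses a fraction of true spots. Class separation
survives (high expressers still count an order of magnitude above
negatives), and exact count recovery is asserted only for cells whose
rendered spots respect the separation radius.

## Segmentation

Otsu foreground on the smoothed round-1 reporter → Euclidean distance
transform, smoothed with σ = 2 px → watershed seeded by the h-maxima
(prominence 0.5 px) of the smoothed distance map → area filter (default
50–2000 px² at 0.5 µm/px). Prominence-based seeding keeps one seed per
elongated cell body — the distance ridge of a thin diagonal wedge carries
many 0.3–0.5 px pixelation maxima that fragment plain peak seeding — while
still splitting genuinely touching cells across a thin neck. The programmatic
segmenter replaces interactive curation so the pipeline is automatable;
imported hand-curated label TIFFs are first-class and validated on load.

## Correlative statistics

IF positivity uses Otsu's between-class-variance criterion evaluated
exactly over the sample splits (histogram-binned Otsu is unreliable for
tens of cells); a fixed manual threshold is also supported. The ROC is the
empirical curve over observed feature values, AUC by trapezoid (it equals
the Mann–Whitney U statistic over n₁n₂, asserted to 1e-9 in tests), and the
operating threshold maximizes Youden's J with ties resolved toward the
lower threshold. Receptor classes come from per-gene positivity patterns
with thresholds at the 95th percentile (configurable) of the Tas1R counts
observed in CA4+ control cells. Nerve adjacency is a dilation test with a
2 µm default radius — "adjacent" is never quantified in the underlying
procedure, so the radius is a declared parameter reported in outputs.
Dual-tuned nerve attribution: intrinsic if any adjacent cell expresses all
three receptors (intrinsic takes precedence, matching the
primary-driver interpretation), spillover if a sweet and an umami cell are
both adjacent without a dual cell, otherwise unexplained; categories are
mutually exclusive and exhaustive.

## Pipeline

Stages (simulate → segment → register → traces → spots → integrate) each
write their outputs plus a manifest with parameters and SHA-256 checksums of
inputs and outputs; a missing upstream file is a dependency error naming the
stage. Everything is deterministic for a fixed config and seed (asserted by
checksum in the tests). The `corrtaste` CLI is a thin wrapper over
`corrtaste.pipeline`.

## Validation problem sizes

The bundled experiments run at desk scale: the deformation benchmark uses a
256×256 bud of 30 cells (80 µm, the upper end of the modeled range) with a
2 px maximum warp and 3% noise; the rigid benchmark a 192×192 bud of 12
cells at 3°/(15, −10) px, 5% noise, 0.8 attenuation; tuning recovery uses
200 buds of 8 cells at 96×96 with amplitude 0.5 and 2% noise. These sizes
were chosen so the full validation runs in minutes while keeping every
quantity (cell packing, spot density per cell, warp magnitude relative to
cell size) at the modeled scale.

## Known limitations

2D per-plane processing throughout (no 3D PSF, no volumetric registration);
no spot decomposition in dense clusters; no affine/similarity registration
models; nerve ROIs are user-supplied polygons (no fiber segmentation);
expression calling degrades when very few control cells are present, since
a percentile of two or three counts is a weak threshold.
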