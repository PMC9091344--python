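# Methods

## Coordinate and unit conventions

Frames are `[row, column]` arrays; flow runs along columns (x), the lateral
direction across the channel is the row axis (y). The channel interior is a
band of rows (`ChannelGeometry.channel_span_px`, default rows 10–89 of a
100-row field of view), flanked by darker wall pixels. The normalized
lateral position is |y/W| with y measured from the channel centerline and
W = 11 µm the channel width; 0 is the centerline, 0.5 the wall. Defaults:
pixel size 0.1375 µm/px (so W spans exactly 80 px and an |y/W| tolerance of
0.01 corresponds to 0.8 px), frame rate 400 Hz, field of view 100 × 800 px.
The field of view is wide enough that the fastest cells (10 mm/s ≈ 182
px/frame at 400 Hz) stay fully visible for at least four frames, which the
minimum track length of 3 requires.

## Synthetic data generator

The generator realizes, with recorded ground truth, the statistical
structure the analysis assumes. It is a statistical emulator, not a
hydrodynamic simulation: shapes and equilibrium positions are imposed by
the model below, not solved from membrane mechanics.

**Shape mixture.** Cell velocities are uniform on a configurable range
inside the 0.1–10 mm/s operating envelope (default 0.5–10 mm/s; the lower
cut keeps sequence lengths practical, since transit time scales as 1/v).
With probability `fraction_pathological` a cell is one of the five
pathological classes (uniformly); otherwise it is a slipper with
probability σ((v − v_c)·k) — logistic crossover, default v_c = 6 mm/s,
k = 1 (mm/s)⁻¹ — and a croissant otherwise. The logistic form encodes a
gradual dominance change around the crossover; its steepness is a free
parameter of the emulator.

**Lateral positions.** Croissants and pathological classes sit on the
centerline plus Gaussian jitter (sd 0.02 |y/W|, clipped at ±3 sd); slippers
at ±0.125 ± 0.02 (clipped to [0.05, 0.25]), sign uniform. Clipping keeps
every silhouette strictly inside the channel. Downstream statistics use
|y|, so the sign is unobservable.

**Rendering.** Each class is a parametric implicit silhouette at the 8 µm
cell scale (croissant: ellipse with an axial bite, mirror-symmetric about
the flow axis; slipper: flatter ellipse with an off-axis bite; acanthocyte:
7 marginal spicules; echinocyte: 14 shallow undulations; sphere; 3-lobed
multilobe; bent-rod "other"). Silhouettes are anti-aliased by subpixel
supersampling, recentered so the nominal placement coordinate equals the
silhouette's center of mass (important for asymmetric shapes), drawn dark
(grey 90) on a bright channel background (grey 200) between darker walls
(grey 120), and degraded with additive Gaussian sensor noise (default sd 4
grey levels) before 8-bit quantization. The five pathological geometries
are package constants chosen to be morphometrically separable at the
default scale; they stand for the variety of pathological morphologies, not
for any specific atlas.

**Arrivals.** Cells enter upstream one after another with a random
edge-to-edge gap (150 px minimum plus an exponential excess, mean 300 px);
the entry scheduler also guarantees the gap never falls below the minimum
when a faster cell follows a slower one. This keeps the sample dilute
(matching sub-percent hematocrit) while letting a ~2000-frame sequence
carry ~200 cells across the whole velocity range.

**Ground truth.** Per cell: class, velocity, signed and absolute lateral
offset, entry frame. Per cell-frame: the sub-pixel center of mass of the
rendered silhouette and a flag marking frames where the cell is fully
inside the field of view (partial cells at the left/right border are
discarded by the detector by design, so recall is defined over fully
visible observations). Everything is bit-for-bit reproducible from the
seed.

**Presets** fix the study conditions per cohort: `control` has no
pathological admixture; `nas` 40% (centered pathological shapes, so the
high-velocity off-center peak collapses); `hdf-pre`/`hdf-post` 15%/35%;
`storage-week-N` restricts velocities to 8–10 mm/s and sets the
pathological (centered) fraction so the expected non-slipper/slipper ratio,
normalized to a fresh control, equals 1 + slope·week — inverted in closed
form from the mean slipper probability over the window.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical blur and illumination gradients, cell
deformation dynamics within a track (tank-treading, swinging), overlapping
cells, focus drift, within-class biological shape variability beyond
orientation/scale/pose jitter, and camera artifacts beyond additive
Gaussian noise. Accuracy numbers on synthetic data are upper bounds for
instrument data.

## Detection and tracking

Background: per-pixel temporal median over an evenly strided subsample of
≤ 256 frames (each pixel is cell-free in well over half of them in the
sparse regime). Segmentation: background-subtracted darkening thresholded
at k = 5 robust sigmas (1.4826 × MAD of the difference image); connected
components within 300–4000 px² (an 8 µm cell at the default scale covers
≈ 950–1400 px²) become detections; components touching the left/right
border are partial cells and are dropped. Centroids are intensity-weighted
on the background-subtracted image, which is what makes the 0.01 |y/W|
(0.8 px) error budget attainable at W = 80 px.

Linking is greedy gated nearest-neighbor, justified by single-file dilute
flow: a link must advance downstream by a step consistent with the expected
velocity range (default 0.1–10 mm/s, with a small margin), stay within an
8 px lateral gate, and — once a track has a step history — within 35% of
its previous step. Candidates are resolved per frame pair in ascending
cost (downstream advance plus 4× the lateral offset), one successor per
detection. The step gate's upper bound (≈ 202 px) is deliberately below
the minimum possible inter-cell spacing (≥ 208 px), so cross-cell links are
geometrically excluded. Tracks shorter than 3 frames are dropped; velocity
is the OLS slope of x versus time over the whole track (averaging pixel
quantization noise), and tracks with non-positive velocity are rejected
(flow is unidirectional). |y/W| is averaged over a track's detections;
detections outside the channel span are flagged and excluded. Channel walls
can be located from the background intensity profile (midpoint crossing
between wall and interior levels) when the span is not given in metadata.

## Shape classifier

Preprocessing (shared by all backends): estimate the crop's background
level from its border pixels, convert to a positive cell signal regardless
of the crop's polarity (raw bright-field or background-subtracted),
peak-normalize, resize to 48 × 48. Two backends sit behind one interface:

* `moments` (default): Otsu-segmented silhouette of the preprocessed crop;
  features are area fraction, circularity, eccentricity, solidity, extent,
  a mirror-symmetry IoU about the flow axis (the croissant/slipper
  discriminator), and the seven signed-log Hu moments; a standardized
  linear discriminant does the 7-way classification. Deterministic, trains
  in seconds, and fully interpretable.
* `mlp`: a single-hidden-layer dense network (96 units) on the 28 × 28
  downsampled pixel crop, deterministic given its seed. Higher capacity;
  useful as a cross-check that does not share the hand-crafted features.

Training reports held-out accuracy on a stratified 80/20 split. On the
fixed synthetic benchmark (7 × 300 training, 7 × 60 test crops with
orientation/pose/scale/subpixel/noise augmentation) the moments backend
reaches ≈ 1.00 and the mlp backend ≈ 0.97 overall accuracy; training crops
include both 180°-rotated poses because slippers face either wall.
Per-track labels are a majority vote over up to 5 central-frame crops, ties
broken by the larger mean probability. Probability vectors always lie on
the 7-class simplex in a fixed class order (which also breaks argmax ties).
Models serialize to a joblib file plus a JSON sidecar (config, class order,
training-set hash, schema version).

## Statistics

* **Densities.** |y/W| histograms on 0.02-wide bins over [0, 0.5]; smoothed
  densities by Gaussian KDE with reflection at both boundaries, Silverman
  bandwidth floored at 0.01 (the floor keeps near-degenerate samples from
  collapsing to spikes); unit integral by trapezoidal normalization.
  Velocity bins are half-open (lo, hi], width 1 mm/s over (0, 10]; a
  track's bin comes from its fitted velocity. Empty bins raise an
  empty-distribution signal and are never zero-filled.
* **Reference and deviation.** The control reference is the per-bin
  pointwise mean of control densities, renormalized. The deviation score is
  the per-bin L1 distance (range [0, 2]) averaged — not summed — over
  populated bins in 1–10 mm/s, so samples with missing bins remain
  comparable; the mean-vs-sum and metric choices are deliberate design
  decisions of this package.
* **Ratios.** Shape ratio = pathological/healthy counts in a velocity
  window (1–10 mm/s by default; 1–3 mm/s in the dialysis preset); storage
  ratio = non-slipper/slipper counts over 8–10 mm/s. Zero denominators
  raise an undefined-ratio signal that serializes as null, never 0 or
  infinity.
* **Transition velocity.** Midpoint of the first bin where the slipper
  fraction exceeds the croissant fraction and stays higher in every later
  populated bin; none-signal otherwise.
* **Storage trends.** Ratios are normalized by a fresh control, fitted by
  OLS per donor; the shared threshold is the mean of all donors' fitted
  values at the reference week — default week 7 (49 days, the expiry of
  standard additive-solution concentrates), configurable to week 6 since
  both conventions appear in practice. The crossing week solves
  fit(w) = threshold exactly and is null when the fit does not reach the
  threshold within the observed span plus 4 weeks.
* **Group comparison.** One-way ANOVA plus Tukey HSD (scipy), with
  significance stars at 0.05/0.01. Calibration is verified by simulation:
  the type-I error at α = 0.05 under a Gaussian null stays within
  [0.03, 0.07] over 1000 replicates.

## Numerical and design notes

* Degenerate inputs: constant crops yield a valid (low-confidence)
  probability vector; NaN or empty crops are rejected; a density of
  identical values falls back to the bandwidth floor; two identical groups
  give p ≈ 1; all-zero-variance groups raise a degenerate-data error.
* Determinism: a single integer seed drives the generator; every CLI stage
  is byte-identical under a repeated seed; classifier training is
  deterministic given its seed.
* Problem sizes in the test suite (a 200-cell tracking benchmark, 2100/420
  crop classifier benchmark, 2500-cell phase diagram, 20-seed paired cohort
  comparisons, 2 × 10⁵ cells per storage time point) were chosen as the
  smallest sets at which the binomial/OLS error of each check is comfortably
  inside its acceptance band.
* Known limitations: one capillary per run (no multi-channel stitching), no
  within-track deformation dynamics, no transfer to real micrographs
  without retraining, raw softmax/LDA probabilities are not calibrated
  uncertainties.
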