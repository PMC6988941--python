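# Methods

## Phosphene model

The simulated percept approximates reports from retinal-implant wearers:
each stimulated electrode elicits a circular gray dot with a Gaussian
luminance profile, brightest at its center and decaying toward the
periphery. The model is a deterministic function of the processed stimulus,
a grid configuration, and a dropout seed, in four stages:

1. **Sampling.** The stimulus raster is partitioned into `rows × cols`
   equal rectangular tiles (the last row/column of tiles absorbs remainder
   pixels when the image size is not divisible by the grid); each
   electrode's drive is the arithmetic mean of its tile. Mean pooling was
   chosen over max pooling because the direct baseline is defined by
   brightness *averaging* over each phosphene's region, and the sampling
   stage is shared by all methods.
2. **Quantization.** `level = round(drive · (L−1))` with exact half-values
   rounded up. Half-up is a deliberate, documented tie-break: it makes the
   quantizer deterministic across platforms (banker's rounding would map
   0.5 · (L−1) differently depending on parity) and idempotent on
   intensities already of the form `k/(L−1)`.
3. **Dropout.** Each electrode is independently dead with probability
   `dropout_rate` (default 0.10, the standard figure for implant electrode
   failure). One mask is drawn per session and reused for every frame —
   dead electrodes are a property of the implant, not of the stimulus — and
   the mask is bit-reproducible from `(config, seed)`.
4. **Rendering.** A live electrode at level `ℓ > 0` paints an isotropic
   Gaussian dot at its lattice point with peak `ℓ/(L−1)` and
   `σ(ℓ) = sigma_fraction · spacing · ℓ/(L−1)`, truncated at
   `truncate_sigmas · σ`. Both brightness and radius therefore grow
   linearly with the level; linear size scaling is the simplest reading of
   "size and brightness proportional to intensity" and is configurable.
   Overlapping dots combine by pointwise maximum, which keeps the output in
   [0, 1] without renormalization; summation would saturate clusters of
   bright dots. Defaults `sigma_fraction = 0.25`, `truncate_sigmas = 3`
   make adjacent max-level dots just touch at 2σ, giving a dense but
   non-merging array. Background pixels beyond every truncation radius are
   exactly 0.

Default configuration: 32 × 32 grid (1024 sites), 8 levels including off,
10% dropout, 20° simulated field of view, 512 px square output.

## Stimulus methods

**Direct** converts the scene to luminance (ITU-R BT.601 weights,
`0.299 R + 0.587 G + 0.114 B`) and passes it through unchanged; the
per-phosphene averaging lives in the sampling stage.

**Edge** runs the scikit-image Canny detector at its default parameters
(σ = 1, default hysteresis thresholds) on the luminance image and dilates
the binary edges with a radius-1 disk. The structuring element is a disk
(the detector is isotropic, so the thickening should be too); the dilation
radius is exposed.

**SIE-OMS** is assembled in four steps:

1. *Filtering*: instances whose class is outside the indoor set
   {chair, table, couch, toilet, bath, sink, bed, oven, microwave,
   refrigerator, laptop} are discarded.
2. *Stacking*: instances are sorted by ascending confidence (stable in
   input order on ties). Detection confidence falls with occlusion, so
   painting in this order lets confident (near) objects overwrite the
   objects they hide — a painter's algorithm with confidence as a depth
   proxy.
3. *OMS rendering*: each mask interior is painted at gray 0.5 and its
   silhouette — a band 2 px wide just **inside** the mask boundary,
   obtained as `mask ∧ ¬erosion(mask, disk(2))` — at 1.0. Keeping the
   contour inside the mask makes the painter's output exactly equal to a
   per-pixel z-buffer (top instance by `(score, index)`, then contour
   test), which is the oracle the tests check against. The painted image
   is finally smoothed by grayscale morphological closing with a radius-1
   disk to reduce aliasing; the gray levels, contour width and smoothing
   radius are all parameters, since only "white silhouettes, gray masks"
   is prescribed.
4. *Composition*: the structural-edge probability map is binarized at 0.5,
   thickened by a disk dilation to roughly 2 px, drawn at full white, and
   then every nonzero OMS pixel overwrites it — edges are always
   background, object masks always foreground. Full-white edges were
   chosen because the schematic examples show bright layout lines; the
   level is a parameter.

Scenes are resampled so the short side is 512 px before any method runs
(masks and edge maps nearest-neighbour alongside), comfortably above the
32 × 32 grid.

## Synthetic scenes

The generator exists so that the full pipeline and the experiment can be
exercised with exact ground truth and no external data. Each scene is a
box-room interior in one-point perspective: a pinhole camera on the room
axis (4 × 2.8 × 6 m room, camera at 1.5 m) projects the cuboid's
wall/floor/ceiling intersection segments, which are rasterized both into
the ground-truth edge map (exactly, as line segments) and faintly into the
rendered image; floor, walls and ceiling are filled at distinct gray
shades scaled by a lighting-contrast factor. Objects are parametric
silhouettes composed of rectangles and ellipses (toilet = bowl ellipse +
tank box, table = top + legs, ...), placed on the floor band with nearer
objects lower in the frame and larger. Per room category the class pool is
fixed (bathroom ⊇ {toilet, sink, bath}, etc.) and 2–4 objects are drawn,
always including the room's signature object.

Occlusion is resolved by painting back-to-front; each instance's stored
mask is its **visible** region, and its confidence score is
`clip(1 − 0.8 · occluded_fraction + ε, 0, 1)` with `ε ~ U(−0.05, 0.05)`.
The slope 0.8 and noise ±0.05 are package choices: the model only needs
confidence to correlate negatively with occlusion (the premise of
confidence-ordered stacking), which the tests verify as Spearman ρ < −0.5
over 200 scenes. Everything is deterministic given the seed; batch
generation spawns per-scene seeds from a master seed.

What the generator does *not* emulate: texture, shading gradients,
photographic noise, perspective foreshortening of the object silhouettes
themselves, and detector failure modes (missed or hallucinated objects —
scores are noisy but every annotated object exists). Passing tests
therefore demonstrate the correctness of the pipeline's geometry,
compositing, quantization and bookkeeping on clean segmentations, not
robustness to real detector output.

## Experiment scheduling and scoring

A trial plan draws `images_per_subject` distinct scenes per subject (no
subject sees a scene twice under any method), assigns methods in a
balanced shuffled interleaving, and inserts a pause marker after every
15th stimulus (so 54 images yield pauses after items 15, 30 and 45). The
stimulus pool (300 scenes × 3 methods) exceeds what one subject views, so
subjects overlap in the stimuli they see; the balancing strategy is a
package choice since only the per-subject count is prescribed.

Object recognition is graded per image: a trial is NA when unanswered,
correct when at least one reported class matches a ground-truth class
after synonym mapping (oven ≡ microwave, whose rectangular silhouettes are
indistinguishable; "dining table"/"desk" → table; "sofa" → couch; the
table is user-editable), otherwise incorrect. Unknown class strings raise
a validation error naming the offender rather than being silently dropped.

Room identification accumulates a 6 × 7 contingency table (actual room ×
predicted room + NA). Recall has two variants: *answered-only* divides the
diagonal count by the row's answered trials; *total* divides by all trials
of the row. NA is never a prediction, so precision is always
`correct_c / predicted_c` over raw counts and is shared by both variants.
Percentages are reported to 2 decimals with half-up rounding; zero
denominators yield an explicit undefined (`None`), never 0. The per-method
summary reports proportions of correct/incorrect/NA with a 95% normal-
approximation confidence half-width `1.96 · sqrt(p(1−p)/n)` on pooled
trials; the interval method is a package choice as only "95% confidence
intervals" is prescribed. A paired t-test across subjects is provided as
an exploratory convenience only.

## Problem sizes and numerical notes

The test suite exercises the full study bookkeeping (300 scenes, 900
stimulus images) directly, and estimates the dropout fraction over 10,000
seeded masks; both complete in well under the times a desk check needs.
Distributional checks use 3-standard-error bands (binomial moments of the
dead-electrode count). Degenerate inputs are rejected loudly: empty
rasters, out-of-range intensities, images smaller than the electrode grid,
shape mismatches between masks, edge maps and stimuli, and trial plans
that exceed the scene pool.
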