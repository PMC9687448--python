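# Methods

`octovessel` implements a two-stage pipeline for detecting coronary
microvessels in polar-domain intravascular OCT (IVOCT) pullbacks: semantic
segmentation of microvessel *candidates* followed by a shallow-CNN
classifier that rejects residual false positives, with cross-frame track
linking and quantification on top. Because clinical IVOCT data with expert
microvessel labels are not publicly available, the package ships a synthetic
phantom generator that emulates every structure the pipeline must detect or
reject, so every stage is testable end to end with exact ground truth.

## Imaging geometry and the microvessel definition

A pullback is a stack of polar frames indexed (frame, A-line, depth). The
A-line axis θ is circular — row 0 is adjacent to the last row, one catheter
rotation per frame — and the depth axis r is radial distance from the
catheter, 5 µm per pixel by default (1.5 mm = 300 pixels). At 180 frames/s
and 36 mm/s pullback speed, consecutive frames are 0.2 mm apart; track
length is therefore `n_frames × 0.2 mm`.

A **microvessel** is a signal-poor tubuloluminal structure with no
connection to the vessel lumen that persists over consecutive frames.  Two
mandatory negatives follow from the definition: **side branches** (dark, but
contiguous with the lumen) and short-lived speckle artifacts (dark, but not
persistent).  **Calcifications** (sharp-bordered dark plaque regions) are
further confusers that the candidate classifier must reject.

## Phantom generator

Each frame is built from a smooth lumen boundary b(θ) (mean radius plus
low-order angular harmonics, drifting slowly along the pullback).  Tissue
beyond the boundary follows a depth-attenuated mean profile
`I0·exp(−μ·(r−b))` (I0 = 0.85, μ = 0.012 px⁻¹) modulated by multiplicative
gamma speckle with shape 4 (a standard OCT speckle surrogate; mean 1,
σ/μ = 0.5).  Structures:

- **Microvessels**: elliptical tubes whose centres drift ≤ 1.5 px/frame over
  3–12 consecutive frames; interiors are multiplied by 0.18.  Radii default
  to 4–10 px (40–100 µm at 5 µm/px), the scale of the diameters reported
  for IVOCT microvessels (~100 µm, overestimated by the resolution limit).
  Only these pixels are labelled positive.
- **Side branches**: dark wedges (×0.12) extending from the lumen boundary
  over several frames — lumen-contiguous by construction, labelled "other".
- **Calcifications**: larger ellipses with a crisp dark plateau (speckle
  suppressed inside, sharp border), labelled "other".
- **Guidewire**: a bright arc at the lumen over a circular A-line interval
  of 18–30 A-lines, with everything beyond attenuated ×0.10 (the shadow).

Structures are placed by rejection sampling with angular margins so they do
not overlap each other or the guidewire shadow.  What the phantom does *not*
emulate: catheter non-uniform rotational distortion, blood artifacts,
multi-layer wall anatomy (intima/media/adventitia), realistic plaque
texture, or signal-to-noise variation with depth of focus.  Passing the
phantom benchmark therefore demonstrates that the pipeline machinery is
correct and learnable at realistic geometry and contrast; it does not
certify clinical performance.

Two presets: `desk` (256 A-lines × 200 depth px, 40 frames) for CPU-scale
training and tests, and `fidelity` (496 × 360) matching the full geometry.
All randomness flows from one integer seed; identical parameters and seed
give bit-identical output.

## Pre-processing

Five deterministic steps per frame, in order: guidewire blanking, lumen
detection, pixel shifting, ROI cropping, Gaussian denoising (7×7 kernel,
σ = 1 px, reflected borders).  Bookkeeping (per-A-line shift offsets, the
blanked interval, a validity mask) makes the alignment invertible and lets
ground-truth labels ride through the identical transform.

- **Lumen boundary**: the published pipeline delegates this to an external
  learned model; here a deterministic baseline fills the interface (which is
  pluggable): per A-line, the first depth past the catheter mask where the
  angularly smoothed intensity exceeds an Otsu threshold for ≥5 consecutive
  pixels, then dynamic-programming smoothing over θ with a ±3 px step limit.
  The circular boundary condition is enforced by anchoring the DP at several
  candidate start depths (percentiles of the raw estimates) and requiring
  the path to close within the step limit.  On phantoms the mean absolute
  boundary error is well under 3 px.
- **Guidewire**: each A-line contributes a score — normalized beyond-lumen
  darkness relative to a shadow threshold (0.55) minus a bright
  leading-reflection bonus — and every circular interval of width 10–40 is
  scored by the sum, so the minimum covers exactly the dark band.  Across
  frames a Viterbi pass over the top per-frame candidates adds a
  centre-drift penalty (γ = 0.02/A-line).  An interval is reported empty
  when no A-line falls below the shadow threshold.  Blanked pixels are set
  to 0 and excluded from training losses via the validity mask.
- **Pixel shift** moves each A-line left so tissue starts at depth 0; the
  right side is zero-padded and flagged invalid.  This normalizes lesion
  appearance and turns lumen contact into a depth-0 test for the track
  stage.

## Candidate segmentation network

The segmenter follows the atrous/ASPP encoder–decoder family: a
separable-convolution encoder (entry stride-2 stage, one stride-2 separable
stage, a dilation-2 separable tail; batch normalization and ReLU after every
convolution; output stride 4), an atrous spatial pyramid pooling block
merging a 1×1 branch, 3×3 branches at rates 8/16/32 and an image-level
pooling branch, and a decoder that upsamples to the stride-2 skip, refines,
and restores full resolution with a final 3×3 refinement convolution.  The
analytic receptive field of the default configuration is 291 px ≥ the
256×200 desk frame, so every output pixel sees the whole image (the
image-pooling branch is global on top of that).  The network is deliberately
small (~14k parameters): it trains on one CPU in minutes, and the phantom
task does not reward capacity.

The networks run on a compact numpy engine written for this package
(`octovessel.nn`): im2col-based dilated/grouped convolution, batch norm,
max pooling, separable bilinear resizing, Adam, and explicit backprop —
verified in the test suite against brute-force convolution and numerical
gradients.

## Training protocol

Both networks share one protocol: Adam; initial learning rate 0.001 dropped
by ×0.2 every drop period; L2 weight penalty (1e-5); at most 50 epochs;
early stop when validation loss fails to improve by more than 0.01%
(relative) over five consecutive epochs.  Class weights for the segmentation
loss are the inverse median frequency of the class proportions,
`w_c = median(f)/f_c`, and pixels invalidated by blanking or padding are
excluded from the loss.

The drop period is configurable because its natural unit is ambiguous: a
drop period of 0.5 *epochs* — the literal protocol default — multiplies the
rate by 0.2 twice per epoch, which freezes learning within ~2 epochs on any
task; the schedule helper accepts fractional or integer epoch periods, and
the benchmark uses a 6-epoch period so the stepped schedule family is
preserved at a trainable rate.

**Crop sampling.** Microvessel pixels are ~0.1% of a frame.  Training on
whole frames pushes the inverse-median-frequency weights to ~1:770, and the
argmax of a model trained that way operates at an extremely permissive
posterior threshold.  The benchmark therefore trains on 48×48 crops —
half vessel-centred with ±8 px jitter, half random background — which
raises the positive frequency to ~2% and the weights to a trainable range
while leaving the network fully convolutional at inference.  The operating
probability threshold is then chosen on the *validation* segments
(maximizing pooled Dice over a fixed grid); held-out test segments play no
part in that choice.

## Candidate classification

Connected components of the binary candidate mask (8-connectivity, circular
across the θ edge) become candidates.  Each tight bounding box is padded by
3 px of image context (θ wraps, depth replicates), resized bilinearly to
30×30, and classified by a small CNN: three 3×3 convolutions with 8/16/32
filters and stride 2 (BN + ReLU after each), two 2×2 max-pooling layers
after the first two convolutions, one fully connected layer, softmax over
two classes (6066 parameters).  During training, microvessel patches are
rotated at 30°–180° in 30° steps (seven-fold multiplication); negatives
are never augmented, so a 1:7 class ratio becomes 1:1.  When the segmenter
yields too few false-positive candidates to reach 1:7, the benchmark tops
up negatives with vessel-free context boxes sampled from the same training
segments.  Rejected candidates are erased from the mask; the cleaned mask
is always a subset of the input mask.

## Track linking and quantification

Per-frame blobs are linked greedily: blobs in consecutive frames join a
track iff their pixel sets share ≥1 pixel, ties broken by largest overlap
then smallest circular centroid distance; each blob joins at most one
track.  The consensus definition then rejects tracks spanning fewer than
`min_frames` (default 3) consecutive frames ("too short") and tracks with
any pixel at shifted depth 0–1 ("lumen-connected" — side branches fail
here by construction).  "More than three continuous frames" can be read as
≥3 or ≥4; the default is 3 and the threshold is configurable.  Kept tracks
report length `n_frames × frame pitch` and a mean equivalent-circle
diameter `2·√(area/π) × radial pixel size`; the angular pixel pitch varies
with radius and is ignored, consistent with single-number diameters.

## Evaluation

Pixel metrics are sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total and Dice 2TP/(2TP+FP+FN), counted over valid pixels and
pooled per fold; undefined ratios are flagged and excluded from
aggregation (mean ± sd over folds).  Cross-validation folds group strictly
by segment: segments are shuffled into five near-equal subsets (122
segments → 24/24/24/25/25), each subset serves as the test set of one fold,
and the remainder splits ~82/18 into train/validation.  Frame-level
agreement reports |#manual − #auto| / #manual × 100 plus false-positive and
false-negative frame fractions on both the manual-count and all-frames
bases (both are emitted because the published convention is ambiguous).
Observer agreement combines least-squares regression with R², Bland–Altman
bias and ±1.96·sd limits, and an area Dice 2·Σmin(a,b)/Σ(a+b); group
comparisons use the paired t-test.

## The reference benchmark

`octovessel.benchmark.run_benchmark(seed)` is the package's fixed-seed
experiment: 20 desk-preset pullbacks (40 frames each) split by segment into
14 train / 3 validation / 3 test; 1200 training crops, 20 epochs; the
classifier trained on the segmenter's own candidates.  At seed 1 it reaches
held-out pixel Dice ≈ 0.71 before candidate filtering and ≈ 0.77 after,
classifier patch accuracy ≈ 0.98, recovers every generated tube as a kept
track, and rejects every side branch.  These sizes were chosen so the full
benchmark runs in about ten minutes on a single CPU core; the numbers above
are recomputed, not stored, by `scripts/acceptance.py` and the test suite.

## Numerical and design choices

- Frame raster fixed as (A-line row, depth column); 0-based indices,
  half-open intervals; circular intervals carried as (start, width).
- Convolution borders: reflection for denoising; zero + invalid flag for
  shifts and crops; SAME padding inside the networks.
- Integer rasters are normalized to [0,1] by their dtype maximum on load;
  pullbacks are written as float32 TIFF (bit-exact round trip).
- Guidewire fill value is 0 with an invalid flag, matching the black strip
  convention; labels under the blank are dropped from the loss rather than
  relabelled.
- Blob area has no minimum by default (a config gate exists but is off).
- Determinism: every stochastic stage takes an explicit seed; two runs with
  the same configuration and seed produce identical phantoms, initial
  weights, shuffles, loss histories and candidate tables.

## Known limitations

- The lumen baseline is a threshold-plus-DP heuristic; frames whose lumen
  is atypical (e.g. fully shadowed) fall back on DP interpolation.
- The phantom's speckle is spatially white before smoothing; real OCT
  speckle is correlated with the point-spread function, so real false
  positives are harder than phantom ones.
- Track linking requires strictly consecutive frames; a single fully missed
  frame splits a track (mitigated by high per-frame sensitivity on
  phantoms, but a gap-tolerant linker would be the next step).
- The classifier sees 30×30 context patches only; it cannot use
  cross-frame persistence, which is left to the track stage.
- Input-gradient saliency on a model this small is dominated by the deep,
  strongly attenuated (dark) tissue band rather than by individual
  detections — darkness is the dominant learned evidence everywhere.  The
  map is still useful for spotting padding/blanking artifacts (invalid
  pixels are zeroed), but it does not localize single vessels the way
  saliency from large pretrained backbones does.
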