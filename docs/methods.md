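# Methods

`nepcount` implements a perception pipeline for automatically detecting,
tracking and counting Norway lobster (*Nephrops norvegicus*) passing in
front of a uniformly colored, opaque, high-contrast background — the
observation geometry of an enclosed monitoring section inside a demersal
trawl, where a colored tarpaulin sheet presents a static scene to a fixed
camera under artificial light. This note documents the models, the
parameters that matter, the synthetic data used to exercise them, and the
design choices made where the method left them open.

## Detection: three cues fused by AND

Each frame passes through three independent foreground filters whose binary
masks are multiplied elementwise; a pixel survives only if all three agree.

**Gaussian-mixture background subtraction.** Every pixel's RGB history is
modelled online by K = 5 Gaussian components in the Stauffer–Grimson style:
per-channel means, one shared variance per component, weights summing to
one. Components are ranked by weight/σ; the top-ranked components whose
cumulative weight reaches the *minimum background ratio* (0.64) constitute
the background model. An incoming pixel matches a component when its
squared color distance is within 2.5²·C·σ² (C = 3 channels); a pixel whose
best-ranked match is not a background component — or that matches nothing —
is foreground. The first 140 frames are a training window (learning rate
1/t, a running average); afterwards the rate is fixed at 0.005. Unmatched
pixels replace the lowest-weight component with a fresh one (initial weight
0.05, initial σ = 30/255). The raw mask is cleaned by binary opening with a
3×3 square and closing with a 15×15 square. The model runs on RGB rather
than grayscale because the green background is deliberately near-isoluminant
with the red animal (complementary colors): a luminance-only model cannot
see the target at all. The update rule exists twice — a plain numpy
reference and a numba kernel used in production — and the test suite asserts
they agree bitwise on random frame streams.

**Red-minus-gray thresholding.** Crustacean carapace reflects red-band
light (astaxanthin), so the red channel minus the Rec.601 luminance
(0.2989 R + 0.5870 G + 0.1140 B, full-precision weights summing to 1)
isolates chromatically red content; values are clipped at zero and
thresholded at 1% of full scale (0.01 on the internal [0, 1] intensity
convention).

**Mean-shift + CLAHE red thresholding.** Subtracting each pixel's channel
mean from its channels removes achromatic content and leaves pixels
dominated by a single primary; clipping to [0, 1] and restoring contrast
with CLAHE (clip limit 0.01, 8×8 tiles) makes the surviving red response
comparable across illumination; the red channel is thresholded at 0.05
(the method prescribes only "a low threshold"; the value is configurable).
CLAHE acts independently per channel, so only the red channel — the only
one consumed downstream — is actually equalized; the result is identical
to equalizing all three and extracting red.

**Blob analysis.** 8-connected components of the fused mask with at least
7500 pixels (at the reference 1920×1440 resolution) become detections with
tight bounding box, pixel-mean centroid and area. An optional
`resolution-scaled` mode multiplies the area gate by the actual-to-reference
pixel-count ratio (e.g. 833 px at 480×640) so the same relative gate applies
to desk-scale frames.

## Tracking and counting

Targets are assumed to translate at near-constant velocity (animals tumble
through the net with the current and cannot swim against it), so each track
carries a first-order Kalman filter on state (x, y, vx, vy) with
accelerations fixed at zero and position-only measurements. Defaults
(pixels²): initial position/velocity covariance diag(200, 200, 50, 50),
process noise diag(100, 100, 25, 25), measurement noise 100, initial
velocity zero.

Per frame: predict all tracks; assign detections to predicted positions by
the Hungarian algorithm on a Euclidean cost matrix padded with a
non-assignment cost of 150 px (pairings costlier than not pairing are
dropped); update matched filters; age unmatched tracks and mark them lost
after 10 consecutive misses; seed a new track from every unassigned
detection. Track ids are never reused.

Every unique track is a counting candidate. To keep one-frame noise tracks
out of the tally, a confirmation gate requires at least 8 frames with an
assigned detection and a detection rate of at least 0.6 over the track's
visible span (creation to last assignment — a coasting tail after the
animal leaves the image does not dilute the rate). Tracks still active at
the end of the video are counted if they pass the gate.

## Single-image segmentation (background-color evaluation)

Four methods behind one interface, all returning a binary mask plus
diagnostics, used to compare candidate background colors (green, yellow,
orange, white) by the Jaccard index against ground truth:

- **Edge (LoG zero crossings).** Grayscale → Gaussian smoothing (σ_s = 1.5·σ,
  with σ = 2 px the LoG scale) → Laplacian-of-Gaussian → zero-crossing
  pixels whose local slope exceeds the mean |LoG| response → closing with a
  disk-5 → border-connected hole filling → opening with the same disk to
  remove the closing band. The slope gate is relative to the mean response
  so flat sensor noise does not produce speckle edges.
- **Graph cut.** CIE-Lab with histogram-equalized L → SLIC superpixels
  (600 segments, compactness 1.0 on Lab-scale channels) → region-adjacency
  graph on mean color with similarity weights exp(−d²/σ_sim), σ_sim = 100 →
  recursive normalized cut (threshold 0.001). Superpixel compactness is the
  accuracy-limiting parameter: at compactness 10 the superpixel lattice
  cannot follow the thin claw limbs and caps the achievable Jaccard near
  0.7 regardless of the cut, while compactness ~1 adheres to the color
  boundary. Foreground identification: the cut partitions touching the top
  image rows are background (the same top-of-image background convention
  used to label random-forest training data); everything else is
  foreground; if every partition touches the top row the smallest one is
  foreground; a single-partition outcome is reported degenerate with an
  empty mask.
- **Random forest.** HSV with CLAHE-equalized V; per-pixel features H, S,
  V_eq plus two texture channels (5×5 local standard deviation and 9×9
  local entropy of V_eq); 50 trees; training labels from a square
  foreground box centered on the animal and the first 100 image rows as
  background; at most 10 000 training pixels per class, subsampled with the
  given seed; fully deterministic given the seed. The default box is
  100×100 px (appropriate when the animal spans most of a paper-scale
  crop); on the desk-scale synthetic stills, whose target is ~50 px tall,
  fixtures use a 24 px box so the foreground labels actually lie on the
  animal — the label geometry scales with the subject, not the image.
- **Instance-mask plugin.** An adapter for any external instance
  segmentation backend (e.g. a pretrained Mask R-CNN): all returned
  instance masks are merged by binary OR and class labels are ignored. No
  backend is bundled; calling without one raises a capability error, and
  nothing else in the package requires one.

## Evaluation

- **Jaccard index** J = |X∩Y| / |X∪Y| between predicted and ground-truth
  masks. Two empty masks raise an error rather than scoring 1 — the
  labeling protocol has no empty ground truth.
- **Precision / recall / F** from per-video TP/FP/FN counts, with 0/0 cases
  reported as 0 and flagged degenerate. The headline aggregation averages
  per-video F-scores after rounding each to 2 decimals — the arithmetic
  that reproduces a printed summary of 2-decimal table rows (the raw
  average differs in the third decimal); both rounded and raw modes are
  exposed.
- **Track matching** (for synthetic runs, standing in for a human
  supervisor): an automatic track matches a ground-truth trajectory when
  its centroid is within a 50 px gate (defined at 1920×1440, scaled with
  linear frame size) for at least half of their overlapping frames. Each
  matched trajectory is one TP; extra automatic tracks on an
  already-matched trajectory are FPs (one animal detected as several);
  automatic tracks matching nothing are FPs; unmatched trajectories FNs.
- **Contrast diagnostics**: chi-squared (with the ½ factor) and Euclidean
  distances between 256-bin normalized grayscale histograms, and
  foreground/background separability as the Euclidean or pooled-covariance
  Mahalanobis distance between mean RGB vectors (ridge 1e-6 when singular).

## Synthetic scenes

The generator emulates the experimental tank footage, not open-water
imagery: a uniformly colored opaque background (presets for the four
tarpaulin colors), a smooth static illumination gradient (default amplitude
0.10, brighter toward the top where the light sits), i.i.d. Gaussian pixel
noise (default σ = 0.01), and one or more elongated reddish targets
(polygonal body-plus-claws silhouettes, ~4:1 aspect, area ≈ 0.4·scale²,
body color near RGB (0.65, 0.25, 0.20) with ±0.05 jitter) entering one side
and translating at near-constant velocity (default 3 px/frame ± 0.5
jitter at 480×640 — the apparent speed of material drifting past at the
~2-knot flow of the towing scenario, scaled to the small frame). Default
frames are 480×640 at 30 fps for desk-scale runs; a paper-scale 1440×1920
configuration is a one-line change (`size=(1440, 1920)`, fixed area gate).
Contrast presets {low, med, high} blend the target color toward the
background color (factors 0.25 / 0.55 / 1.0) for monotonicity experiments.
Ground truth (instance masks, tight boxes, track ids, centroid
trajectories, total count) is exact by construction, and all randomness
flows through seed sequences: the same spec renders bitwise-identical
videos.

What the generator does *not* emulate: turbidity and backscatter, mobilized
sediment, fish bycatch, shadows, occluding groups of animals (an optional
overlapping-entry configuration exists for regression experiments but is
excluded from quality gates), and camera auto-exposure/white-balance
drift. Passing the synthetic gates therefore demonstrates the pipeline's
correctness and its behavior under the idealized high-contrast scene — not
performance on real trawl footage.

## Numerical and interface choices

- All processing on [0, 1] float intensities; 8-bit I/O divided by 255. The
  1% red threshold reads as 0.01 on this scale (identical masks either way).
- Coordinates 0-based, origin top-left, x = column; boxes (x, y, w, h),
  half-open.
- Grayscale uses the full-precision Rec.601 weights so that (1,1,1) maps to
  exactly 1.0; the rounded textbook values agree to 4 decimals.
- Square-SE morphology is computed with separable moving min/max filters
  (identical to erosion/dilation with the square, O(N)); closing pads the
  frame first so it remains extensive at borders, matching the
  infinite-plane set definition (enforced against a brute-force
  neighborhood-scan oracle in the tests).
- Hungarian assignment solves the (T+D)×(D+T) padded square matrix; with
  ties the matching follows `scipy.optimize.linear_sum_assignment`.
- GMM component ranking breaks weight/σ ties toward the lower component
  index (stable sort) in both implementations.
- Video I/O: directories of numbered PNG frames are the primary format and
  always available; MP4/AVI containers are attempted through imageio and
  raise a clean I/O error if no ffmpeg backend is installed.
- Problem sizes in the default test run and the acceptance script (desk
  scale, chosen once): 480×640 scenes, 300-frame videos, 20 videos in the
  count-recovery suite (10 in the script), 10 stills per background preset
  (2 per preset in the script), 600 superpixels.

## Known limitations

- The blob detector is only semi-semantic: occluding animals merge into one
  blob (undercounting) and partial detections can split one animal into
  several tracks (overcounting) — the confirmation gate suppresses only the
  short-lived splits.
- The GMM needs its training window before any detection is possible;
  animals present during training are absorbed into the background model.
- The normalized-cut foreground rule assumes the animal does not touch the
  top image row.
- Real-footage wall-clock throughput and real-image segmentation scores are
  out of scope here: the package is exercised on synthetic scenes only.
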