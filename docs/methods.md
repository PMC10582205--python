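# Methods

## Problem setting and pipeline model

An embryo-evaluation video interleaves four kinds of material: blurry
setup frames, per-drop focus ramps, clear two-embryo observation phases,
and blurred embryo-free transitions while the microscope moves between
growth-medium drops. The pipeline's model is that *detection count over
time* is sufficient to recover the session structure: embryos are detected
in (ramp and) clear frames and absent from setup/transition frames, so
maximal runs of detected frames correspond one-to-one to medium drops.

### Frame stream

Videos are downsampled by frame dropping: keep source indices that are
multiples of `stride = round(source_fps / target_fps)`, starting at 0.
Frame dropping (rather than temporal averaging) is chosen because it is
deterministic, introduces no resampling artifacts, and preserves the exact
pixel content the detectors and the blur scorer see. Defaults: 25 fps
capture, 5 fps working rate, so `stride = 5`. A non-integer rate ratio is
rounded with a logged warning. Grayscale conversion uses BT.601 luma
weights (`0.299 R + 0.587 G + 0.114 B`), the de-facto standard of the
imaging toolchain this pipeline interoperates with.

### Detection contract

Detection is pluggable because the production-quality stage is a trained
neural detector whose weights are site-specific. The package ships:

* a **classical detector**: grayscale → Gaussian smooth (σ = 2 px) →
  local-contrast map (local standard deviation, 9-px window) → Otsu
  threshold → morphological closing (disk radius 5) → hole filling →
  connected components, keeping components with area between 0.5% and 25%
  of the frame and circularity `4πA/P² ≥ 0.6`; confidence = circularity.
  The hole-filling step matters: the contrast map rings an embryo's
  boundary, and filling turns the ring into the solid blob whose tight
  bounding box is wanted.
* a **reader** for the normalized YOLO text dialect
  `class cx cy w h [conf]` (one `.txt` per frame, `frame_%06d.txt`),
  converted to pixel corner coordinates; missing confidence defaults
  to 1.0, malformed lines fail loudly with their line number.

Boxes are continuous; IoU is computed on continuous areas and equals
pixel-count IoU exactly for integer-coordinate boxes.

### Segmentation and organization

A bookkeeping state machine tracks `folder_count` (starting at 1),
`start_frame`/`stop_frame` and a gap counter. A naive reading of the
folder-creation logic never closes a segment once opened, which would make
a second Medium folder impossible; this implementation therefore closes a
segment after `gap_frames` consecutive detection-free frames (default 5,
i.e. 1 s at 5 fps — shorter than typical inter-drop transitions, longer
than single-frame detector dropouts) and additionally at end of stream.
Closed segments shorter than `min_len_frames` (default 5) are discarded as
spurious and do not consume a Medium index.

Within a frame, the two embryos are ordered by bounding-box x-center
(ties by y-center); with more than two detections the top-2 by confidence
are kept, since each drop holds exactly two embryos. A lone detection is
assigned to the side whose running-mean x-center is nearer (default left
with no history); re-evaluating sides each frame with a running-mean
memory tolerates single-frame jitter better than freezing the assignment
at the first frame. Crops are taken from the full-resolution downsampled
frames, rounded outward to integer bounds, clamped to the frame, and
written as JPEG quality 95 into
`Day_{day}/D{day}_{NNN}/Medium_{MM}/Embryo_{EE}/image_{KK}.jpg`
(2-digit zero-padded, growing naturally past 99).

### Blur filtering

Sharpness is the population variance (divide by `N = H·W`) of the response
of the 3×3 Laplacian kernel `[[0,1,0],[1,−4,1],[0,1,0]]` applied with
mirror padding that does not duplicate the edge pixel. These conventions
(population vs sample variance, −4-center sign, padding) are fixed so
scores are bit-stable; a direct double-loop convolution oracle in the
test-suite pins them. A crop is *clear* iff its score lies inside the
day band, inclusive on both edges so the configured bounds are attainable:
day 3 → [500, 2000], day 5 → [300, 900]. Keeping an upper bound departs
from the common one-sided variance blur test; it is retained deliberately,
as it rejects crops dominated by debris or specular edges. Scores are
computed on the crop as saved (post-JPEG), because filtering runs after
organization, on the stored library. Filtering modes: `delete`,
`quarantine` (move to a `_blurry` sibling) or `dry_run`; survivors are
renumbered gaplessly, and a second pass removes nothing.

### Evaluation

Greedy confidence-ordered matching: per frame, each detection in
descending confidence claims its best-IoU unmatched ground-truth box if
the IoU reaches the threshold (TP, box consumed) else is an FP; leftover
ground-truth boxes are FNs. AP is the exact area under the precision
envelope of the confidence-ranked PR curve — all-point interpolation
rather than 11- or 101-point sampling, because the exact envelope is
reproducible and threshold-free. mAP@0.5:0.95 averages the ten thresholds
0.50…0.95 (step 0.05). AP with zero ground-truth boxes is an error, not 0.
Reported precision/recall are at IoU 0.5 with no confidence cutoff.

## Synthetic sessions

The generator renders embryos as drifting disks (radius 42 px in a
320×240 frame, ±3 px sinusoidal drift) filled with a granular,
thresholded smoothed-noise speckle on a flat background (level 185) with
mild sensor noise (σ = 1.5), and applies the scripted per-phase Gaussian
blur (setup σ = 6, ramps 6 → 1.5, transitions σ = 5, clear phases σ = 0).
The speckle is essential: Laplacian-variance separation requires genuine
high-frequency content inside the embryo. Its contrast is day-dependent
(±16 gray levels for day 3, ±7 for day 5), chosen once so that clear-phase
crops score inside the default bands at the default rendering scale
(day 3 ≈ 1500–1850 post-JPEG; day 5 ≈ 750–870) while ramp/transition
crops score below 100. The default session script is 16 s of setup, then
per drop a 1.2 s focus ramp and a clear phase whose durations cycle
through 15 s, 4 s and 7.2 s — the dwell pattern of a session in which a
good embryo is examined at length and a poor one dismissed quickly — with
2 s transitions between drops. All randomness flows through one seeded
`numpy` generator; identical (script, seed) pairs are bit-identical.

`calibrate_band` repeats the experimental band-setting procedure on
synthetic material: the band spans the 0.5th–99.5th percentile of
clear-crop scores widened by 10%, and calibration *fails* (raises) when
more than 5% of blurred crops fall inside the band or fewer than 10 crops
per class exist — inseparable classes are reported, not papered over.

### What the generator does and does not emulate

It reproduces the temporal phase structure, the two-embryos-per-drop
geometry, focus blur, sensor noise and the sharp/blurred score contrast.
It does not attempt photorealistic embryo morphology, cell-division
events, illumination drift, debris, or occlusion. Passing tests therefore
demonstrate that the *pipeline logic* (segmentation, side assignment,
folder layout, blur banding, metric computation) is correct under the
stated assumptions — not that the classical detector or the printed bands
transfer to clinical footage, where a trained detector and per-site band
calibration are expected.

## Problem sizes and numerical choices

Tests run on short sessions (2–3 s phases) for unit checks and on
default-timing sessions (≈ 160–250 frames at 5 fps, 320×240) for the
recovery and end-to-end suites: drop/folder recovery uses drops ∈ {1,2,3}
× seeds 0–4; the end-to-end filter check calibrates on seeds 100–101 and
evaluates on held-out seeds 0–4, requiring ≥ 95% of clear-phase crops kept
and ≥ 95% of blurred-phase crops removed. Recovery suites drive the
organizer with manifest-derived detections so their outcome is not
confounded by detector recall, which is asserted separately (≥ 90% at
IoU 0.5 on clear frames). Degenerate inputs are handled explicitly:
constant frames yield no detections and score exactly 0; empty detection
streams organize to an empty report; zero-area crops after clamping are
skipped with a warning.

## Known limitations

* The classical detector is tuned to high-contrast disk-like embryos; on
  real footage it is a smoke-test stand-in for a trained detector
  supplied through the detection-file interface.
* Embryo identity is not tracked across drops or between day-3 and day-5
  sessions; left/right assignment is per-drop only.
* Encoded-video decoding depends on the imageio plugins available in the
  host environment; the frame-directory input path is always available.
* One patient per video; multi-patient batching is out of scope.
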