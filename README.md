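# embryosort

Turn time-lapse microscopy videos of group-cultured embryos into an
organized, quality-filtered library of per-embryo image crops.

In IVF laboratories, embryos are cultured in pairs inside droplets of
growth medium and evaluated under an inverted microscope on day 3 and
day 5 of development. A recorded evaluation session is one long video with
a characteristic structure: blurry setup frames while the microscope is
positioned, then — for each medium drop — a short focus ramp followed by a
clear observation phase showing the two embryos side by side, with
blurred, embryo-free transition frames between drops. Building image
datasets from such footage by hand is slow and error-prone; `embryosort`
automates it for embryologists and machine-learning practitioners who need
clean per-embryo image sets.

## What it does

1. **Frame extraction** — decodes a video (or a directory of numbered
   frames) and downsamples it from the capture rate (typically 25 fps) to
   a working rate (default 5 fps) by keeping every
   `round(source_fps / target_fps)`-th frame.
2. **Detection** — locates embryos per frame. Detection is a pluggable
   contract: a built-in weight-free blob detector (local-contrast map,
   Otsu threshold, morphology, connected components filtered by area and
   circularity), or externally produced detections in the normalized YOLO
   text dialect `class cx cy w h [conf]`.
3. **Segmentation & organization** — partitions the detection stream into
   segments (maximal runs of detected frames = one medium drop each) with
   hysteresis closure, assigns the two embryos of each frame to left/right
   slots by bounding-box x-centers, and writes crops into
   `Day_{3|5}/D{day}_{NNN}/Medium_{MM}/Embryo_{EE}/image_{KK}.jpg`.
4. **Blur filtering** — scores each crop by the population variance of its
   3×3 Laplacian response, `Var(∇²I)`, and keeps it only if the score lies
   inside an inclusive day-specific band: **[500, 2000]** for day-3
   embryos, **[300, 900]** for day-5. Sharp, textured crops score high;
   defocused crops score low; implausibly high variance is also rejected.
5. **Evaluation** — scores any detector against ground truth with greedy
   confidence-ordered IoU matching, precision/recall, and exact-envelope
   average precision: mAP@0.5 and mAP@0.5:0.95 (thresholds 0.50–0.95,
   step 0.05).
6. **Simulation** — a seeded generator renders microscope-like sessions
   (textured embryo disks, scripted per-phase Gaussian blur) with a
   per-frame ground-truth manifest, so the whole pipeline is testable
   without clinical data.

## Worked example

```bash
python examples/02_organize_and_filter.py
```

simulates a two-drop day-3 session, organizes it with the classical
detector and blur-filters the tree:

```
segments found  : 2
  Medium_01: frames 80-160 (16.0 s)
  Medium_02: frames 171-196 (5.0 s)
embryo folders  : 4, crops written: 214
blur filter     : kept 190, quarantined 24
  Day_3/D3_001/Medium_01/Embryo_01: 81 crops, variance 21-1458
  ...
```

Two drops become `Medium_01` and `Medium_02`, each with an `Embryo_01`
(left) and `Embryo_02` (right) folder. The 24 quarantined crops are the
focus-ramp frames, whose Laplacian variance (≈ 20–70) falls below the
day-3 lower bound of 500; clear-phase crops score ≈ 1400 and are kept.

The other examples show session simulation (`01`), detector evaluation
(`03` — the classical detector reaches mAP@0.5 = 1.000 on clear synthetic
frames but loses AP above IoU 0.80 because its boxes are only
approximately tight), and experimental band calibration (`04`).

The same pipeline is available as a CLI:

```bash
embryosort simulate --drops 3 --seed 0 --out video/
embryosort organize video/ --day 3 --patient D3_001 --out library/
embryosort classify library/ --day 3 --mode quarantine
```

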