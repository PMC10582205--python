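"""Score a detector against ground truth with mAP@0.5 and mAP@0.5:0.95.

Runs the classical detector on the clear frames of a synthetic session and
scores it against the manifest's true boxes. An ideal detector reaches
mAP 1.0 at every threshold; a real one loses AP at the strict thresholds
first, because its boxes are only approximately tight.
"""

from embryosort import default_script, detect_classical, generate_video, map_range
from embryosort.detector import BoundingBox

frames, manifest = generate_video(default_script(n_drops=1, day=3), seed=0)

clear = [mf for mf in manifest.frames if mf.phase == "clear"]
gts = {mf.frame_index: [BoundingBox(*b["box"]) for b in mf.boxes] for mf in clear}
preds = [detect_classical(frames[mf.frame_index]) for mf in clear]

rep = map_range(preds, gts)
print(f"frames evaluated: {len(clear)}, ground-truth boxes: {rep.n_ground_truth}")
print(f"precision       : {rep.precision:.3f}  recall: {rep.recall:.3f}  (IoU 0.5)")
print(f"mAP@0.5         : {rep.map50:.3f}")
print(f"mAP@0.5:0.95    : {rep.map5095:.3f}")
for thr, ap in rep.ap_by_threshold.items():
    print(f"  AP@{thr:.2f}: {ap:.3f}")
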