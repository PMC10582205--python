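"""Run the full pipeline: simulate, organize into folders, blur-filter.

Organizes a 2-drop session into the Day/Patient/Medium/Embryo tree using
the built-in classical detector, then removes blurry crops with the
default day-3 Laplacian-variance band (500-2000). The printed counts show
one Medium folder per drop, two Embryo folders per Medium, and the
blur filter discarding focus-ramp crops while keeping clear-phase crops.
"""

import tempfile
from pathlib import Path

from embryosort import (
    default_script,
    detect_classical,
    filter_tree,
    generate_video,
    organize,
)

frames, manifest = generate_video(default_script(n_drops=2, day=3), seed=0)
det_stream = [detect_classical(f) for f in frames]

out = Path(tempfile.mkdtemp()) / "library"
report = organize(frames, det_stream, day=3, patient="D3_001", out_root=out,
                  target_fps=manifest.fps)
print(f"segments found  : {len(report.segments)}")
for seg in report.segments:
    print(f"  Medium_{seg.drop_index:02d}: frames {seg.first_frame}-{seg.last_frame} "
          f"({seg.duration_s(manifest.fps):.1f} s)")
print(f"embryo folders  : {report.n_folders}, crops written: {report.total_crops}")

filt = filter_tree(out, day=3, mode="quarantine")
print(f"blur filter     : kept {filt.kept}, quarantined {filt.removed}")
for folder, entries in sorted(filt.folders.items()):
    scores = [e["score"] for e in entries if e["score"] is not None]
    print(f"  {folder}: {len(entries)} crops, variance {min(scores):.0f}-{max(scores):.0f}")
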