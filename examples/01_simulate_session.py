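"""Generate a synthetic embryo-evaluation session and inspect its structure.

Renders a 3-drop microscope session (blurry setup, per-drop focus ramp and
clear observation phase, blurred transitions) and prints the phase layout
recorded in the ground-truth manifest.
"""

from collections import Counter

from embryosort import default_script, generate_video

script = default_script(n_drops=3, day=3)
frames, manifest = generate_video(script, seed=0, fps=5.0)

print(f"frames rendered : {len(frames)}  ({len(frames) / manifest.fps:.1f} s at {manifest.fps:.0f} fps)")
print("phase counts    :", dict(Counter(mf.phase for mf in manifest.frames)))
for first, last in manifest.clear_phase_bounds():
    print(f"clear phase     : frames {first}-{last}  ({(last - first) / manifest.fps:.1f} s)")

# Every clear frame carries two ground-truth boxes, left before right.
mf = next(m for m in manifest.frames if m.phase == "clear")
for b in mf.boxes:
    x0, y0, x1, y1 = b["box"]
    print(f"  {b['side']:>5} embryo box: ({x0:.0f},{y0:.0f})-({x1:.0f},{y1:.0f})")
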