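"""Calibrate a clear/blur variance band from labeled footage.

On real data the band edges are set experimentally; this repeats that
procedure on a synthetic session, then verifies the band on a video the
calibration never saw.
"""

import numpy as np

from embryosort import calibrate_band, default_script, generate_video
from embryosort.synthetic import _crop_scores

frames, manifest = generate_video(default_script(n_drops=3, day=3), seed=100)
lo, hi = calibrate_band(frames, manifest)
print(f"calibrated band : ({lo:.0f}, {hi:.0f})   [default day-3 band: (500, 2000)]")

f2, m2 = generate_video(default_script(n_drops=3, day=3), seed=5)
clear, blurred = _crop_scores(f2, m2)
inside = lambda s: lo <= s <= hi
print(f"held-out seed 5 : {np.mean([inside(s) for s in clear]):.1%} of clear crops inside band")
print(f"                  {np.mean([inside(s) for s in blurred]):.1%} of blurred crops inside band")
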