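"""Shared fixtures: small synthetic sessions and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from embryosort.synthetic import (
    EmbryoSpec,
    Phase,
    SceneScript,
    default_script,
    generate_video,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mini_script(n_drops: int = 1, day: int = 3, width: int = 320, height: int = 240) -> SceneScript:
    """A fast session script: same phase structure as the default, shorter."""
    phases = [Phase("setup_blur", 2.0, 6.0, 6.0)]
    cy = height / 2
    for i in range(n_drops):
        embryos = (
            EmbryoSpec(cx=width * 0.3, cy=cy, radius=42.0,
                       texture_seed=1000 + 10 * i, side="left"),
            EmbryoSpec(cx=width * 0.7, cy=cy, radius=42.0,
                       texture_seed=1001 + 10 * i, side="right"),
        )
        if i > 0:
            phases.append(Phase("transition", 1.6, 5.0, 5.0))
        phases.append(Phase("focus_ramp", 1.2, 6.0, 1.5, embryos, drop_index=i + 1))
        phases.append(Phase("clear", 3.0, 0.0, 0.0, embryos, drop_index=i + 1))
    return SceneScript(phases=tuple(phases), width=width, height=height, day=day)


@pytest.fixture(scope="session")
def mini_video():
    """One-drop fast session, day 3, seed 0: (frames, manifest)."""
    return generate_video(mini_script(1), seed=0)


@pytest.fixture(scope="session")
def three_drop_video():
    """Three-drop fast session, day 3, seed 0: (frames, manifest)."""
    return generate_video(mini_script(3), seed=0)


@pytest.fixture(scope="session")
def default_one_drop_video():
    """Default-timing one-drop session (16 s setup, 15 s clear), day 3."""
    return generate_video(default_script(1, day=3), seed=0)


# ---------------------------------------------------------------------------
# independent oracles


def iou_rasterized(a, b, scale: int = 1) -> float:
    """Pixel-count IoU for integer-coordinate boxes (half-open raster)."""
    xs = range(int(min(a.x_min, b.x_min)), int(max(a.x_max, b.x_max)))
    ys = range(int(min(a.y_min, b.y_min)), int(max(a.y_max, b.y_max)))
    inter = union = 0
    for y in ys:
        for x in xs:
            in_a = a.x_min <= x < a.x_max and a.y_min <= y < a.y_max
            in_b = b.x_min <= x < b.x_max and b.y_min <= y < b.y_max
            inter += in_a and in_b
            union += in_a or in_b
    return inter / union if union else 0.0


def laplacian_variance_bruteforce(gray: np.ndarray) -> float:
    """Direct double-loop 3x3 Laplacian + population variance.

    Mirror padding without duplicating the edge pixel: index -1 maps to 1,
    index H maps to H-2.
    """
    a = np.asarray(gray, dtype=np.float64)
    h, w = a.shape

    def px(y: int, x: int) -> float:
        if y < 0:
            y = -y
        if y >= h:
            y = 2 * h - 2 - y
        if x < 0:
            x = -x
        if x >= w:
            x = 2 * w - 2 - x
        return a[y, x]

    resp = np.empty_like(a)
    for y in range(h):
        for x in range(w):
            resp[y, x] = (
                px(y - 1, x) + px(y + 1, x) + px(y, x - 1) + px(y, x + 1)
                - 4 * px(y, x)
            )
    return float(np.mean(resp**2) - np.mean(resp) ** 2)


def average_precision_bruteforce(records, n_gt: int) -> float:
    """AP from (confidence, is_tp) records via explicit envelope summation.

    Walks the confidence-ranked list rank by rank, computes precision and
    recall at every prefix, and sums recall increments times the maximum
    precision attained at or after that rank.
    """
    ranked = sorted(records, key=lambda r: -r[0])
    precisions, recalls = [], []
    tp = fp = 0
    for conf, is_tp in ranked:
        tp += bool(is_tp)
        fp += not is_tp
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
    ap = 0.0
    prev_r = 0.0
    for k, r in enumerate(recalls):
        best_p = max(precisions[k:])
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap
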