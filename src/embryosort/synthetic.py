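"""Seeded generator of microscope-like embryo videos with ground truth.

An embryo-evaluation session has a characteristic temporal structure: the
video opens with blurry setup frames while the microscope is positioned,
then for each growth-medium drop a short focus ramp is followed by a clear
observation phase showing two embryos side by side, and drops are
separated by blurred, embryo-free transition frames. This module renders
that structure synthetically — embryos as textured disks on a noisy
background, phase blur as a Gaussian of scripted sigma — and emits a
per-frame :class:`Manifest` of phase labels, blur sigmas and true bounding
boxes, so every pipeline stage can be tested without clinical data.

The embryo texture is a thresholded smoothed-noise speckle (granular,
cell-like): sharpness scoring by Laplacian variance requires genuine
high-frequency content inside the disk. Its contrast depends on the
developmental day so that the default clear/blur bands (day 3: 500-2000,
day 5: 300-900) separate in-focus from blurred crops at the default
rendering scale.

All randomness flows through one ``numpy`` generator seeded by the caller;
identical (script, seed) pairs produce bit-identical frames and manifests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from scipy import ndimage

from .detector import BoundingBox, Detection, FrameDetections
from .video_io import Frame

__all__ = [
    "EmbryoSpec",
    "Phase",
    "SceneScript",
    "Manifest",
    "ManifestFrame",
    "generate_video",
    "default_script",
    "calibrate_band",
    "write_frames_dir",
    "CalibrationError",
]

BACKGROUND_LEVEL = 185.0
NOISE_SIGMA = 1.5
# speckle contrast (+/- around the disk base level) per developmental day,
# chosen so clear-crop Laplacian variances land inside the default bands
TEXTURE_AMP = {3: 16.0, 5: 7.0}
DISK_BASE_LEVEL = 128.0


@dataclass(frozen=True)
class EmbryoSpec:
    """One rendered embryo: a drifting textured disk.

    The center path is a slow sinusoidal drift of amplitude
    ``drift_amp_px`` around ``(cx, cy)``, with per-embryo phase offsets
    derived from ``texture_seed``.
    """

    cx: float
    cy: float
    radius: float
    texture_seed: int
    side: Literal["left", "right"]
    drift_amp_px: float = 3.0
    drift_period_s: float = 20.0

    def center_at(self, t_s: float) -> tuple[float, float]:
        rng = np.random.default_rng(self.texture_seed)
        px, py = rng.uniform(0, 2 * math.pi, size=2)
        w = 2 * math.pi / self.drift_period_s
        return (
            self.cx + self.drift_amp_px * math.sin(w * t_s + px),
            self.cy + self.drift_amp_px * math.sin(w * t_s + py),
        )

    def max_extent(self) -> float:
        return self.radius + self.drift_amp_px


@dataclass(frozen=True)
class Phase:
    """One scripted phase of the session."""

    kind: Literal["setup_blur", "focus_ramp", "clear", "transition"]
    duration_s: float
    sigma_start: float = 0.0
    sigma_end: float = 0.0
    embryos: tuple[EmbryoSpec, ...] = ()
    drop_index: int = 0  # 1-based for ramp/clear phases, 0 otherwise

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("phase duration must be positive")

    def sigma_at(self, frac: float) -> float:
        return self.sigma_start + (self.sigma_end - self.sigma_start) * frac


@dataclass(frozen=True)
class SceneScript:
    """Ordered phases plus the frame geometry and developmental day."""

    phases: tuple[Phase, ...]
    width: int = 320
    height: int = 240
    day: int = 3

    def __post_init__(self) -> None:
        for ph in self.phases:
            for e in ph.embryos:
                ext = e.max_extent()
                if not (
                    ext <= e.cx <= self.width - ext
                    and ext <= e.cy <= self.height - ext
                ):
                    raise ValueError(
                        f"embryo at ({e.cx},{e.cy}) r={e.radius} exceeds "
                        f"{self.width}x{self.height} frame bounds"
                    )

    @property
    def n_drops(self) -> int:
        return max((p.drop_index for p in self.phases), default=0)


@dataclass
class ManifestFrame:
    """Ground truth for one frame."""

    frame_index: int
    phase: str
    sigma: float
    drop_index: int
    boxes: list[dict] = field(default_factory=list)  # box, side, blurred


@dataclass
class Manifest:
    """Per-frame ground truth emitted alongside a generated video."""

    fps: float
    width: int
    height: int
    day: int
    frames: list[ManifestFrame] = field(default_factory=list)

    def to_detections(self, include_ramp: bool = True) -> list[FrameDetections]:
        """Oracle detection stream: one confidence-1.0 detection per box.

        Ramp-phase boxes are flagged blurred in the manifest; pass
        ``include_ramp=False`` to keep only clear-phase boxes (e.g. for
        segment-boundary recovery against the clear phases alone).
        """
        stream = []
        for mf in self.frames:
            dets = [
                Detection(box=BoundingBox(*b["box"]), confidence=1.0)
                for b in mf.boxes
                if include_ramp or not b["blurred"]
            ]
            stream.append(FrameDetections(frame_index=mf.frame_index, detections=dets))
        return stream

    def clear_phase_bounds(self) -> list[tuple[int, int]]:
        """(first, last) frame index of each clear phase, in order."""
        bounds: list[tuple[int, int]] = []
        prev = None
        for mf in self.frames:
            if mf.phase == "clear":
                if prev is None:
                    bounds.append((mf.frame_index, mf.frame_index))
                else:
                    bounds[-1] = (bounds[-1][0], mf.frame_index)
                prev = mf.frame_index
            else:
                prev = None
        return bounds

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "fps": self.fps,
                "width": self.width,
                "height": self.height,
                "day": self.day,
                "frames": [
                    {
                        "frame_index": mf.frame_index,
                        "phase": mf.phase,
                        "sigma": mf.sigma,
                        "drop_index": mf.drop_index,
                        "boxes": mf.boxes,
                    }
                    for mf in self.frames
                ],
            },
            **{"indent": 2, **kwargs},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        d = json.loads(Path(path).read_text())
        m = cls(fps=d["fps"], width=d["width"], height=d["height"], day=d["day"])
        for f in d["frames"]:
            m.frames.append(ManifestFrame(**f))
        return m


def _texture_patch(spec: EmbryoSpec, amp: float) -> np.ndarray:
    """Granular speckle texture for one embryo, fixed by its texture_seed."""
    size = int(2 * math.ceil(spec.radius)) + 3
    rng = np.random.default_rng((spec.texture_seed, 7919))
    noise = rng.normal(0.0, 1.0, size=(size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=1.2, mode="mirror")
    return np.where(smooth > 0.0, DISK_BASE_LEVEL + amp, DISK_BASE_LEVEL - amp)


def _render_frame(
    script: SceneScript,
    phase: Phase,
    t_s: float,
    sigma: float,
    textures: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    h, w = script.height, script.width
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
    boxes: list[dict] = []
    for spec in phase.embryos:
        cx, cy = spec.center_at(t_s)
        patch = textures[spec.texture_seed]
        s = patch.shape[0]
        y0, x0 = int(round(cy)) - s // 2, int(round(cx)) - s // 2
        yy, xx = np.mgrid[0:s, 0:s]
        mask = (yy + y0 - cy) ** 2 + (xx + x0 - cx) ** 2 <= spec.radius**2
        region = img[y0 : y0 + s, x0 : x0 + s]
        region[mask] = patch[mask]
        boxes.append(
            {
                "box": [cx - spec.radius, cy - spec.radius, cx + spec.radius, cy + spec.radius],
                "side": spec.side,
                "blurred": phase.kind != "clear",
            }
        )
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=sigma, mode="mirror")
    img += rng.normal(0.0, NOISE_SIGMA, size=img.shape)
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return np.stack([rgb] * 3, axis=-1), boxes


def generate_video(
    script: SceneScript, seed: int, fps: float = 5.0
) -> tuple[list[Frame], Manifest]:
    """Render a scripted session into frames plus a ground-truth manifest."""
    rng = np.random.default_rng(seed)
    amp = TEXTURE_AMP.get(script.day, TEXTURE_AMP[3])
    textures = {
        e.texture_seed: _texture_patch(e, amp)
        for ph in script.phases
        for e in ph.embryos
    }
    frames: list[Frame] = []
    manifest = Manifest(fps=fps, width=script.width, height=script.height, day=script.day)
    index = 0
    for phase in script.phases:
        n = max(1, round(phase.duration_s * fps))
        for k in range(n):
            frac = k / max(1, n - 1) if n > 1 else 1.0
            sigma = phase.sigma_at(frac)
            t_s = index / fps
            pixels, boxes = _render_frame(script, phase, t_s, sigma, textures, rng)
            frames.append(
                Frame(index=index, source_index=index, timestamp_s=t_s, pixels=pixels)
            )
            manifest.frames.append(
                ManifestFrame(
                    frame_index=index,
                    phase=phase.kind,
                    sigma=float(sigma),
                    drop_index=phase.drop_index,
                    boxes=boxes,
                )
            )
            index += 1
    return frames, manifest


CLEAR_DURATION_CYCLE_S = (15.0, 4.0, 7.2)
SETUP_DURATION_S = 16.0
TRANSITION_DURATION_S = 2.0
RAMP_DURATION_S = 1.2


def default_script(
    n_drops: int,
    day: int = 3,
    width: int = 320,
    height: int = 240,
) -> SceneScript:
    """Standard session: ~16 s setup, then per drop a short focus ramp and
    a clear phase (durations cycling 15, 4, 7.2 s), with ~2 s embryo-free
    transitions between drops."""
    if n_drops < 1:
        raise ValueError("n_drops must be >= 1")
    radius = 42.0
    cy = height / 2
    phases: list[Phase] = [Phase("setup_blur", SETUP_DURATION_S, 6.0, 6.0)]
    for i in range(n_drops):
        embryos = (
            EmbryoSpec(cx=width * 0.3, cy=cy, radius=radius,
                       texture_seed=1000 + 10 * i, side="left"),
            EmbryoSpec(cx=width * 0.7, cy=cy, radius=radius,
                       texture_seed=1001 + 10 * i, side="right"),
        )
        if i > 0:
            phases.append(Phase("transition", TRANSITION_DURATION_S, 5.0, 5.0))
        phases.append(
            Phase("focus_ramp", RAMP_DURATION_S, 6.0, 1.5, embryos, drop_index=i + 1)
        )
        clear_s = CLEAR_DURATION_CYCLE_S[i % len(CLEAR_DURATION_CYCLE_S)]
        phases.append(Phase("clear", clear_s, 0.0, 0.0, embryos, drop_index=i + 1))
    return SceneScript(phases=tuple(phases), width=width, height=height, day=day)


class CalibrationError(RuntimeError):
    """Raised when clear and blurred crops cannot be separated."""


def _crop_scores(frames: list[Frame], manifest: Manifest) -> tuple[list[float], list[float]]:
    from .blur_filter import laplacian_variance
    from .video_io import to_grayscale

    clear: list[float] = []
    blurred: list[float] = []
    frame_by_index = {f.index: f for f in frames}
    for mf in manifest.frames:
        fr = frame_by_index.get(mf.frame_index)
        if fr is None or not mf.boxes:
            continue
        gray = to_grayscale(fr)
        for b in mf.boxes:
            x0, y0, x1, y1 = (int(round(v)) for v in b["box"])
            crop = gray[max(0, y0) : y1, max(0, x0) : x1]
            if crop.shape[0] < 3 or crop.shape[1] < 3:
                continue
            (blurred if b["blurred"] else clear).append(laplacian_variance(crop))
    return clear, blurred


def calibrate_band(
    frames: list[Frame],
    manifest: Manifest,
    margin: float = 0.10,
    max_blur_leak: float = 0.05,
) -> tuple[float, float]:
    """Set a clear/blur variance band from a labeled video, as one would
    experimentally on real footage.

    The band spans the 0.5th-99.5th percentile of clear-phase crop scores,
    widened by ``margin`` on both edges so held-out clear crops still fall
    inside. Calibration fails (raises :class:`CalibrationError`) when more
    than ``max_blur_leak`` of the blurred crops land inside the band —
    i.e. the two classes are not separable on this material — or when
    fewer than 10 crops per class are available.
    """
    clear, blurred = _crop_scores(frames, manifest)
    if len(clear) < 10 or len(blurred) < 10:
        raise CalibrationError(
            f"need >= 10 crops per class, got {len(clear)} clear / {len(blurred)} blurred"
        )
    lo = float(np.percentile(clear, 0.5)) * (1.0 - margin)
    hi = float(np.percentile(clear, 99.5)) * (1.0 + margin)
    leak = float(np.mean([(lo <= s <= hi) for s in blurred]))
    if leak > max_blur_leak:
        raise CalibrationError(
            f"classes inseparable: {leak:.0%} of blurred crops inside band ({lo:.0f}, {hi:.0f})"
        )
    return lo, hi


def write_frames_dir(frames: list[Frame], path: str | Path) -> Path:
    """Write frames as frame_%06d.png into *path* (read back by video_io)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for f in frames:
        Image.fromarray(f.pixels, mode="RGB").save(path / f"frame_{f.index:06d}.png")
    return path
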