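"""Per-frame embryo detection: a pluggable contract with two providers.

The production pipeline in the source workflow uses a trained neural
detector; this package treats detection as a contract — a list of
:class:`Detection` per frame — with two built-in providers:

* :func:`detect_classical` — a weight-free blob detector (local-contrast
  map, Otsu threshold, morphology, connected components filtered by area
  and circularity). Adequate for the in-focus, high-contrast embryos the
  synthetic generator renders and for smoke-testing real footage.
* :func:`read_detections` — a reader for externally produced detection
  files in the normalized YOLO text dialect ``class cx cy w h [conf]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .video_io import Frame, to_grayscale

__all__ = [
    "BoundingBox",
    "Detection",
    "FrameDetections",
    "DetectorParams",
    "detect_classical",
    "read_detections",
    "iou",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous pixel coordinates, origin top-left."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def x_center(self) -> float:
        return 0.5 * (self.x_min + self.x_max)

    @property
    def y_center(self) -> float:
        return 0.5 * (self.y_min + self.y_max)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass(frozen=True)
class Detection:
    """One localized embryo with a confidence score in [0, 1]."""

    box: BoundingBox
    confidence: float = 1.0
    label: str = "embryo"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")


@dataclass
class FrameDetections:
    """All detections of one frame; may be empty (transition frames)."""

    frame_index: int
    detections: list[Detection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the classical blob detector.

    Areas are fractions of the frame area; circularity is 4*pi*A/P^2 of the
    connected component (1 for a perfect disk). Defaults are tuned to the
    synthetic generator's default rendering scale.
    """

    gaussian_sigma: float = 2.0
    closing_radius: int = 5
    min_area_frac: float = 0.005
    max_area_frac: float = 0.25
    min_circularity: float = 0.6
    contrast_window: int = 9


def _local_std(gray: np.ndarray, window: int) -> np.ndarray:
    """Local standard deviation via box filters (E[x^2] - E[x]^2)."""
    x = gray.astype(np.float64)
    mean = ndimage.uniform_filter(x, size=window, mode="mirror")
    mean_sq = ndimage.uniform_filter(x * x, size=window, mode="mirror")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def detect_classical(
    frame: Frame, params: DetectorParams | None = None
) -> FrameDetections:
    """Detect embryo-like blobs in one frame without trained weights.

    Pipeline: grayscale -> Gaussian smooth -> local-contrast map (local
    standard deviation) -> Otsu threshold -> morphological closing ->
    connected components -> keep components with plausible area and
    circularity -> tight bounding boxes. Confidence is the component's
    circularity clamped to [0, 1]; results are sorted by descending
    confidence. Deterministic for a fixed frame and params.
    """
    params = params or DetectorParams()
    gray = to_grayscale(frame).astype(np.float64)
    smoothed = ndimage.gaussian_filter(gray, sigma=params.gaussian_sigma, mode="mirror")
    contrast = _local_std(smoothed, params.contrast_window)

    if contrast.max() - contrast.min() < 1e-9:
        return FrameDetections(frame_index=frame.index)
    thr = threshold_otsu(contrast)
    mask = contrast > thr
    if not mask.any() or mask.all():
        return FrameDetections(frame_index=frame.index)
    mask = closing(mask, disk(params.closing_radius))
    # the contrast map rings the embryo boundary; fill to a solid blob
    mask = ndimage.binary_fill_holes(mask)

    frame_area = gray.size
    a_min = params.min_area_frac * frame_area
    a_max = params.max_area_frac * frame_area

    dets: list[Detection] = []
    for region in regionprops(label(mask)):
        area = region.area
        if not a_min <= area <= a_max:
            continue
        perimeter = region.perimeter
        if perimeter <= 0:
            continue
        circ = 4.0 * math.pi * area / (perimeter * perimeter)
        if circ < params.min_circularity:
            continue
        r0, c0, r1, c1 = region.bbox  # half-open row/col bounds
        dets.append(
            Detection(
                box=BoundingBox(float(c0), float(r0), float(c1), float(r1)),
                confidence=min(circ, 1.0),
            )
        )
    dets.sort(key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min))
    return FrameDetections(frame_index=frame.index, detections=dets)


class DetectionFileError(ValueError):
    """Raised for malformed external detection files."""


def read_detections(
    path: str | Path, image_w: int, image_h: int, frame_index: int = 0
) -> FrameDetections:
    """Parse one normalized YOLO-format text file into pixel-space detections.

    Each non-empty line is ``class cx cy w h [conf]`` with cx, cy, w, h
    normalized to [0, 1]; a missing confidence defaults to 1.0. Malformed
    lines or out-of-range values raise :class:`DetectionFileError` naming
    the line number.
    """
    path = Path(path)
    dets: list[Detection] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise DetectionFileError(
                f"{path}:{lineno}: expected 'class cx cy w h [conf]', got {len(parts)} fields"
            )
        try:
            cx, cy, w, h = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise DetectionFileError(f"{path}:{lineno}: non-numeric field") from exc
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h), ("conf", conf)):
            if not 0.0 <= v <= 1.0:
                raise DetectionFileError(
                    f"{path}:{lineno}: {name}={v} outside [0,1]"
                )
        box = BoundingBox(
            x_min=(cx - w / 2) * image_w,
            y_min=(cy - h / 2) * image_h,
            x_max=(cx + w / 2) * image_w,
            y_max=(cy + h / 2) * image_h,
        )
        dets.append(Detection(box=box, confidence=conf))
    return FrameDetections(frame_index=frame_index, detections=dets)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes on continuous coordinates.

    Returns 0.0 for disjoint boxes and 1.0 iff the boxes are identical.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union
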