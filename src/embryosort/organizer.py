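"""Partition a detection stream into growth-medium segments and write the
Day/Patient/Medium/Embryo crop library.

Group-cultured embryos are observed drop by drop: the microscope dwells on
one growth-medium drop (two embryos side by side), then moves through
blurred, embryo-free transition frames to the next drop. A segment — a
maximal run of detected frames — therefore corresponds to one drop and
becomes one ``Medium_MM`` folder; within it the two embryos are told apart
by the x-coordinates of their bounding-box centers (left -> ``Embryo_01``,
right -> ``Embryo_02``) and each detected frame contributes one crop per
side, saved as ``image_KK.jpg``.

Segment closure uses hysteresis: a segment opens at the first detected
frame and closes only after ``gap_frames`` consecutive empty frames (or at
end of stream), so single-frame detector dropouts do not split a drop.
Closed segments shorter than ``min_len_frames`` are discarded as spurious
and do not consume a Medium index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .detector import Detection, FrameDetections
from .video_io import Frame, write_image

__all__ = [
    "Segment",
    "FolderLayout",
    "OrganizerState",
    "OrganizeReport",
    "segment_stream",
    "assign_sides",
    "crop_and_save",
    "organize",
]

DEFAULT_GAP_FRAMES = 5  # 1 s at 5 fps, below typical transition length
DEFAULT_MIN_LEN_FRAMES = 5


@dataclass(frozen=True)
class Segment:
    """A maximal run of detected frames belonging to one growth-medium drop."""

    drop_index: int  # 1-based Medium number
    first_frame: int
    last_frame: int

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError(f"inverted segment: {self}")

    @property
    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1

    def duration_s(self, fps: float) -> float:
        return (self.last_frame - self.first_frame) / fps


@dataclass(frozen=True)
class FolderLayout:
    """Renders Day_{day}/{patient_id}/Medium_{MM}/Embryo_{EE} paths."""

    day: int
    patient_id: str
    medium_index: int
    embryo_index: int

    def __post_init__(self) -> None:
        if self.day not in (3, 5):
            raise ValueError(f"day must be 3 or 5, got {self.day}")
        if self.medium_index < 1 or self.embryo_index not in (1, 2):
            raise ValueError(f"invalid layout indices: {self}")

    def path(self, root: str | Path = ".") -> Path:
        return (
            Path(root)
            / f"Day_{self.day}"
            / self.patient_id
            / f"Medium_{self.medium_index:02d}"
            / f"Embryo_{self.embryo_index:02d}"
        )


def patient_id(day: int, number: int) -> str:
    """Format a patient identifier, e.g. day 3, number 1 -> ``D3_001``."""
    return f"D{day}_{number:03d}"


@dataclass
class OrganizerState:
    """Mutable bookkeeping of the folder-creation state machine."""

    folder_count: int = 1
    start_frame: int = 0
    stop_frame: int = 0
    gap_run: int = 0
    left_history: list[float] = field(default_factory=list)
    right_history: list[float] = field(default_factory=list)


def segment_stream(
    det_stream: Sequence[FrameDetections],
    gap_frames: int = DEFAULT_GAP_FRAMES,
    min_len_frames: int = DEFAULT_MIN_LEN_FRAMES,
) -> list[Segment]:
    """Partition an ordered detection stream into drop segments.

    A segment opens at the first frame with >= 1 detection while none is
    open; its last frame advances with each further detected frame; it
    closes after ``gap_frames`` consecutive empty frames or at end of
    stream. Closed segments shorter than ``min_len_frames`` are dropped
    without consuming a drop index; survivors are numbered 1..n in order.
    """
    if gap_frames < 1 or min_len_frames < 1:
        raise ValueError("gap_frames and min_len_frames must be >= 1")
    raw: list[tuple[int, int]] = []
    open_first: int | None = None
    open_last = 0
    gap = 0
    for fd in det_stream:
        if len(fd) > 0:
            if open_first is None:
                open_first = fd.frame_index
            open_last = fd.frame_index
            gap = 0
        elif open_first is not None:
            gap += 1
            if gap >= gap_frames:
                raw.append((open_first, open_last))
                open_first, gap = None, 0
    if open_first is not None:
        raw.append((open_first, open_last))

    segments = []
    for first, last in raw:
        if last - first + 1 >= min_len_frames:
            segments.append(Segment(len(segments) + 1, first, last))
    return segments


def assign_sides(
    dets: Sequence[Detection], state: OrganizerState
) -> dict[int, Detection]:
    """Map detections of one frame to embryo slots {1: left, 2: right}.

    With two or more detections the top-2 by confidence are kept (each drop
    holds exactly two embryos); the smaller x-center goes left, ties broken
    by smaller y-center. A lone detection is assigned to the side whose
    running mean x-center is nearer, defaulting to left without history.
    The state's side histories are updated with this frame's assignment.
    """
    if not dets:
        raise ValueError("assign_sides requires at least one detection")
    assignment: dict[int, Detection] = {}
    if len(dets) >= 2:
        top2 = sorted(dets, key=lambda d: -d.confidence)[:2]
        a, b = sorted(top2, key=lambda d: (d.box.x_center, d.box.y_center))
        assignment[1], assignment[2] = a, b
    else:
        det = dets[0]
        if state.left_history and state.right_history:
            left_mean = sum(state.left_history) / len(state.left_history)
            right_mean = sum(state.right_history) / len(state.right_history)
            side = 1 if abs(det.box.x_center - left_mean) <= abs(det.box.x_center - right_mean) else 2
        else:
            side = 1
        assignment[side] = det
    if 1 in assignment:
        state.left_history.append(assignment[1].box.x_center)
    if 2 in assignment:
        state.right_history.append(assignment[2].box.x_center)
    return assignment


def crop_and_save(
    frame: Frame,
    det: Detection,
    layout: FolderLayout,
    seq: int,
    root: str | Path = ".",
    pad: int = 0,
    quality: int = 95,
) -> Path | None:
    """Save the detection's crop as ``image_{seq:02d}.jpg`` under *layout*.

    The box is rounded outward to integer bounds, optionally padded by
    ``pad`` pixels, and clamped to the frame. Returns the written path, or
    None (with nothing written) when the clamped crop has zero area.
    """
    import math

    if seq < 1:
        raise ValueError("seq must be >= 1")
    x0 = max(0, math.floor(det.box.x_min) - pad)
    y0 = max(0, math.floor(det.box.y_min) - pad)
    x1 = min(frame.width, math.ceil(det.box.x_max) + pad)
    y1 = min(frame.height, math.ceil(det.box.y_max) + pad)
    if x1 <= x0 or y1 <= y0:
        import logging

        logging.getLogger(__name__).warning(
            "zero-area crop after clamping at frame %d; skipped", frame.index
        )
        return None
    crop = frame.pixels[y0:y1, x0:x1]
    path = layout.path(root) / f"image_{seq:02d}.jpg"
    return write_image(crop, path, quality=quality)


@dataclass
class OrganizeReport:
    """Summary of one organize run: segments found, crops written."""

    day: int
    patient_id: str
    target_fps: float
    segments: list[Segment] = field(default_factory=list)
    crops_per_folder: dict[str, int] = field(default_factory=dict)

    @property
    def n_folders(self) -> int:
        return len(self.crops_per_folder)

    @property
    def total_crops(self) -> int:
        return sum(self.crops_per_folder.values())

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "day": self.day,
                "patient_id": self.patient_id,
                "segments": [
                    {
                        "drop_index": s.drop_index,
                        "first_frame": s.first_frame,
                        "last_frame": s.last_frame,
                        "duration_s": s.duration_s(self.target_fps),
                    }
                    for s in self.segments
                ],
                "crops_per_folder": self.crops_per_folder,
                "total_crops": self.total_crops,
            },
            **{"indent": 2, **kwargs},
        )


def organize(
    frames: Iterable[Frame],
    det_stream: Sequence[FrameDetections],
    day: int,
    patient: str,
    out_root: str | Path,
    gap_frames: int = DEFAULT_GAP_FRAMES,
    min_len_frames: int = DEFAULT_MIN_LEN_FRAMES,
    target_fps: float = 5.0,
    pad: int = 0,
    quality: int = 95,
) -> OrganizeReport:
    """Run the full organization pass: segment, assign sides, save crops.

    ``frames`` and ``det_stream`` must be aligned by frame index. Each
    surviving segment becomes ``Medium_{MM}``; within it every detected
    frame contributes at most one crop per side, numbered gaplessly per
    embryo folder. Deterministic: identical inputs yield an identical file
    set.
    """
    frames = list(frames)
    frame_by_index = {f.index: f for f in frames}
    det_by_index = {fd.frame_index: fd for fd in det_stream}
    segments = segment_stream(det_stream, gap_frames, min_len_frames)
    report = OrganizeReport(
        day=day, patient_id=patient, target_fps=target_fps, segments=segments
    )

    for seg in segments:
        state = OrganizerState(folder_count=seg.drop_index)
        seq: dict[int, int] = {1: 0, 2: 0}
        for idx in range(seg.first_frame, seg.last_frame + 1):
            fd = det_by_index.get(idx)
            frame = frame_by_index.get(idx)
            if fd is None or frame is None or len(fd) == 0:
                continue
            for side, det in sorted(assign_sides(fd.detections, state).items()):
                layout = FolderLayout(day, patient, seg.drop_index, side)
                written = crop_and_save(
                    frame, det, layout, seq[side] + 1, out_root, pad, quality
                )
                if written is not None:
                    seq[side] += 1
                    key = str(layout.path().as_posix())
                    report.crops_per_folder[key] = seq[side]
    return report
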