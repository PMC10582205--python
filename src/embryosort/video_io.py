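"""Frame input/output: decoding, temporal downsampling, grayscale, JPEG writing.

Embryo evaluation videos are captured at a high rate (typically 25 fps) but
consecutive frames are nearly redundant; the pipeline works on a stream
downsampled to a target rate (default 5 fps) by keeping every *stride*-th
source frame, ``stride = round(source_fps / target_fps)``.

Input may be an encoded video (decoded through imageio, when a suitable
plugin is available) or a directory of numbered PNG/JPEG frames — the
codec-free path used throughout the test-suite.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = ["Frame", "VideoMeta", "read_video", "to_grayscale", "write_image"]


@dataclass(frozen=True)
class Frame:
    """One decoded image of the downsampled stream.

    ``index`` counts positions in the downsampled stream; ``source_index``
    is the position in the original stream. ``pixels`` is an H x W x 3
    uint8 array, origin top-left.
    """

    index: int
    source_index: int
    timestamp_s: float
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("Frame.pixels must be an HxWx3 uint8 array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("Frame must be at least 1x1")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class VideoMeta:
    """Summary of a decoded, downsampled stream."""

    source_fps: float
    target_fps: float
    width: int
    height: int
    n_source_frames: int
    n_kept_frames: int

    @property
    def stride(self) -> int:
        return max(1, round(self.source_fps / self.target_fps))


class VideoReadError(RuntimeError):
    """Raised when an input video or frame directory cannot be decoded."""


_FRAME_FILE_RE = re.compile(r"(\d+)")


def _numeric_sort_key(path: Path) -> tuple:
    """Sort frame files by the numeric run(s) in their stem, then name."""
    nums = tuple(int(m) for m in _FRAME_FILE_RE.findall(path.stem))
    return (nums, path.name)


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def _iter_directory(path: Path) -> tuple[list[Path], int]:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}),
        key=_numeric_sort_key,
    )
    if not files:
        raise VideoReadError(f"no PNG/JPEG frames found in directory: {path}")
    return files, len(files)


def read_video(
    path: str | Path,
    target_fps: float = 5.0,
    source_fps: float | None = None,
) -> tuple[VideoMeta, list[Frame]]:
    """Decode *path* and downsample to ``target_fps``.

    Parameters
    ----------
    path
        An encoded video file, or a directory of numbered image frames.
    target_fps
        Rate of the output stream; frames are kept at source indices that
        are multiples of ``stride = round(source_fps / target_fps)``,
        starting at 0.
    source_fps
        Capture rate. Required for frame directories (default 25.0, the
        usual microscope rate); for video files it is read from the
        container metadata, and this argument overrides it if given.

    Returns
    -------
    (VideoMeta, list of Frame)

    Raises
    ------
    VideoReadError
        If the input is missing or undecodable.
    ValueError
        If ``target_fps > source_fps``.
    """
    path = Path(path)
    if not path.exists():
        raise VideoReadError(f"input does not exist: {path}")

    if path.is_dir():
        src_fps = 25.0 if source_fps is None else float(source_fps)
        files, n_source = _iter_directory(path)

        def _iter() -> Iterable[np.ndarray]:
            for f in files:
                with Image.open(f) as im:
                    yield np.asarray(im.convert("RGB"))

        images = _iter()
    else:
        import imageio.v2 as iio

        try:
            reader = iio.get_reader(path)
        except Exception as exc:  # pragma: no cover - depends on plugins
            raise VideoReadError(f"cannot decode video: {path} ({exc})") from exc
        meta = reader.get_meta_data()
        src_fps = float(source_fps if source_fps is not None else meta.get("fps", 25.0))
        images = iter(reader)
        n_source = None  # counted while streaming

    if target_fps <= 0 or src_fps <= 0:
        raise ValueError("frame rates must be positive")
    if target_fps > src_fps:
        raise ValueError(
            f"target_fps ({target_fps}) exceeds source_fps ({src_fps})"
        )
    ratio = src_fps / target_fps
    stride = max(1, round(ratio))
    if abs(ratio - stride) > 1e-9:
        logger.warning(
            "source_fps/target_fps = %.4f is not an integer; using stride %d",
            ratio,
            stride,
        )

    frames: list[Frame] = []
    count = 0
    for source_index, arr in enumerate(images):
        count += 1
        if source_index % stride != 0:
            continue
        rgb = _as_rgb(np.asarray(arr))
        index = len(frames)
        frames.append(
            Frame(
                index=index,
                source_index=source_index,
                timestamp_s=index / target_fps,
                pixels=rgb,
            )
        )
    if n_source is None:
        n_source = count
    if not frames:
        raise VideoReadError(f"no frames decoded from: {path}")

    meta = VideoMeta(
        source_fps=src_fps,
        target_fps=float(target_fps),
        width=frames[0].width,
        height=frames[0].height,
        n_source_frames=n_source,
        n_kept_frames=len(frames),
    )
    return meta, frames


_BT601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: Frame | np.ndarray) -> np.ndarray:
    """BT.601 luma conversion: gray = round(0.299 R + 0.587 G + 0.114 B).

    Accepts a :class:`Frame` or a raw HxWx3 uint8 array; returns an HxW
    uint8 array. Channel-equal pixels map to themselves.
    """
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if px.ndim == 2:
        return px.astype(np.uint8)
    gray = px.astype(np.float64) @ _BT601
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def write_image(pixels: np.ndarray, path: str | Path, quality: int = 95) -> Path:
    """Write *pixels* (HxW gray or HxWx3 RGB, uint8) as a JPEG file.

    Parent directories are created as needed. ``quality`` must lie in
    1..100 (JPEG contract).
    """
    if not 1 <= quality <= 100:
        raise ValueError(f"JPEG quality must be in 1..100, got {quality}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(pixels, dtype=np.uint8)
    mode = "L" if arr.ndim == 2 else "RGB"
    Image.fromarray(arr, mode=mode).save(path, format="JPEG", quality=quality)
    return path
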