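"""Variance-of-Laplacian sharpness scoring and clear/blurry classification.

A blurred image lacks edges and high-frequency content, so the response of
a discrete Laplacian filter is weak and its variance low. Crops are scored
by the population variance of the 3x3 Laplacian response and accepted as
*clear* only inside an inclusive, day-specific band: day-3 embryos use
[500, 2000] and day-5 embryos [300, 900] by default. The upper bound also
rejects images whose variance is implausibly high for a focused embryo
(e.g. frames dominated by debris or hard specular edges).
"""

from __future__ import annotations

import json
import logging
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from scipy import ndimage

from .video_io import to_grayscale

logger = logging.getLogger(__name__)

__all__ = [
    "BlurConfig",
    "laplacian_variance",
    "classify",
    "filter_tree",
    "FilterReport",
]

LAPLACIAN_KERNEL = np.array(
    [[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64
)

DEFAULT_BANDS: dict[int, tuple[float, float]] = {
    3: (500.0, 2000.0),
    5: (300.0, 900.0),
}


@dataclass(frozen=True)
class BlurConfig:
    """Per-day inclusive [lower, upper] variance bands."""

    bands: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        for day, (lo, hi) in self.bands.items():
            if not 0 <= lo < hi:
                raise ValueError(f"invalid band for day {day}: ({lo}, {hi})")

    def band(self, day: int) -> tuple[float, float]:
        try:
            return self.bands[day]
        except KeyError:
            raise KeyError(f"no blur band configured for day {day}") from None


def laplacian_variance(gray: np.ndarray) -> float:
    """Population variance of the 3x3 Laplacian response over all pixels.

    The kernel is ``[[0,1,0],[1,-4,1],[0,1,0]]`` applied with mirror
    padding that does not duplicate the edge pixel; the variance divides by
    N = H*W. Constant images score exactly 0. Images smaller than the
    kernel are rejected.
    """
    arr = np.asarray(gray, dtype=np.float64)
    if arr.ndim == 3:
        arr = to_grayscale(arr.astype(np.uint8)).astype(np.float64)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got {arr.shape}")
    response = ndimage.convolve(arr, LAPLACIAN_KERNEL, mode="mirror")
    return float(np.var(response))


def classify(score: float, day: int, config: BlurConfig | None = None) -> str:
    """Label a sharpness score as ``"clear"`` or ``"blurry"``.

    Clear iff ``lower <= score <= upper`` for the day's band (inclusive on
    both edges, so the configured bounds themselves are attainable).
    """
    config = config or BlurConfig()
    lo, hi = config.band(day)
    return "clear" if lo <= score <= hi else "blurry"


@dataclass
class FilterReport:
    """Outcome of one filter_tree pass."""

    mode: str
    day: int
    folders: dict[str, list[dict]] = field(default_factory=dict)
    kept: int = 0
    removed: int = 0
    errors: int = 0

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "day": self.day,
                "kept": self.kept,
                "removed": self.removed,
                "errors": self.errors,
                "folders": self.folders,
            },
            **{"indent": 2, **kwargs},
        )


_IMAGE_RE = re.compile(r"^image_\d+\.jpe?g$", re.IGNORECASE)


def _score_file(path: Path) -> float:
    with Image.open(path) as im:
        gray = np.asarray(im.convert("L"))
    return laplacian_variance(gray)


def filter_tree(
    root: str | Path,
    day: int,
    config: BlurConfig | None = None,
    mode: Literal["delete", "quarantine", "dry_run"] = "quarantine",
) -> FilterReport:
    """Score every organized crop under *root* and act on the blurry ones.

    Walks the organizer layout for ``image_NN.jpg`` files, scores each with
    :func:`laplacian_variance` and classifies it against the day band.
    Blurry images are deleted (``delete``), moved to a ``_blurry`` sibling
    directory (``quarantine``) or only reported (``dry_run``). Surviving
    clear images are renumbered gaplessly ``image_01.. image_k`` in score
    order of their original sequence. Unreadable images are counted and
    logged, never fatal. A second pass over an already filtered tree
    removes nothing.
    """
    if mode not in ("delete", "quarantine", "dry_run"):
        raise ValueError(f"unknown mode: {mode}")
    config = config or BlurConfig()
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"not a directory: {root}")
    report = FilterReport(mode=mode, day=day)

    folders = sorted(
        {p.parent for p in root.rglob("image_*") if _IMAGE_RE.match(p.name)}
    )
    for folder in folders:
        if folder.name == "_blurry":
            continue
        entries: list[dict] = []
        keep_files: list[Path] = []
        images = sorted(
            (p for p in folder.iterdir() if _IMAGE_RE.match(p.name)),
            key=lambda p: p.name,
        )
        for img in images:
            try:
                score = _score_file(img)
            except Exception as exc:
                logger.warning("unreadable image %s: %s", img, exc)
                report.errors += 1
                entries.append(
                    {"filename": img.name, "score": None, "label": "error", "action": "skipped"}
                )
                continue
            label = classify(score, day, config)
            if label == "clear":
                action = "kept"
                keep_files.append(img)
                report.kept += 1
            else:
                report.removed += 1
                if mode == "delete":
                    action = "deleted"
                elif mode == "quarantine":
                    action = "quarantined"
                else:
                    action = "would_remove"
            entries.append(
                {"filename": img.name, "score": score, "label": label, "action": action}
            )
        report.folders[str(folder.relative_to(root))] = entries

        if mode == "dry_run":
            continue
        for img, entry in zip(images, entries):
            if entry["action"] == "deleted":
                img.unlink()
            elif entry["action"] == "quarantined":
                qdir = folder / "_blurry"
                qdir.mkdir(exist_ok=True)
                shutil.move(str(img), str(qdir / img.name))
        # renumber survivors gaplessly, preserving order
        for seq, img in enumerate(keep_files, start=1):
            target = folder / f"image_{seq:02d}.jpg"
            if img != target:
                img.rename(target)
    return report
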