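"""Periocular region-of-interest extraction.

Pupil localization operates on a small patch around one eye.  When the input
is a full facial image together with a face bounding box (from any external
face detector), the patch is cut out with fixed anthropometric fractions of
the box: the left-eye patch starts at (20 %, 30 %) of the box width/height,
the right-eye patch at (60 %, 30 %), and both are 25 % x 20 % of the box in
size.  Coordinates are 0-based with x = column, y = row, origin at the
top-left pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger("pupilloc")

#: Smallest patch the pipeline can process: the self-similarity stage discards
#: a 10-pixel border on every side and needs a usable interior behind it.
MIN_PATCH_SIZE = 24

# Anthropometric crop fractions of the face box (x-start, y-start, width, height).
LEFT_EYE_FRACTIONS = (0.20, 0.30, 0.25, 0.20)
RIGHT_EYE_FRACTIONS = (0.60, 0.30, 0.25, 0.20)


class DegenerateInputError(ValueError):
    """Input too small or otherwise unusable for the requested operation."""


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face bounding box in source-image pixel coordinates."""

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"face box must have positive size, got {self.w}x{self.h}")


@dataclass(frozen=True)
class PeriocularPatch:
    """A cropped eye region plus the offset of its origin in the source image."""

    image: np.ndarray
    offset_x: int
    offset_y: int
    side: str  # "left" | "right"


def _as_gray_image(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("grayscale image must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a PNG/PGM/BMP raster as a float64 intensity field in [0, 1].

    Color inputs are converted to luminance; 8-bit values map to v/255 and
    16-bit values to v/65535; floating-point rasters are taken as-is.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.width == 0 or im.height == 0:
                raise DegenerateInputError(f"zero-sized raster: {path}")
            if im.mode == "F":
                arr = np.asarray(im, dtype=np.float64)
            elif im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64) / 65535.0
            else:
                arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    except FileNotFoundError as exc:
        raise IOError(f"cannot read image file: {path}") from exc
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise IOError(f"cannot decode image file: {path}") from exc
    return _as_gray_image(np.clip(arr, 0.0, 1.0))


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def crop_periocular(source: np.ndarray, box: FaceBox, side: str) -> PeriocularPatch:
    """Crop one eye's periocular patch out of ``source`` using the face box.

    The crop is clipped to the source bounds (with a logged warning); a patch
    that clipping shrank below ``MIN_PATCH_SIZE`` in either dimension is
    rejected.  Unclipped crops keep the size the percentages dictate — the
    processing stages enforce their own margin-based preconditions.
    """
    source = _as_gray_image(source)
    H, W = source.shape
    if not (0 <= box.x0 and 0 <= box.y0 and box.x0 + box.w <= W and box.y0 + box.h <= H):
        raise ValueError(f"face box {box} does not lie inside the {W}x{H} source image")
    if side == "left":
        fx, fy, fw, fh = LEFT_EYE_FRACTIONS
    elif side == "right":
        fx, fy, fw, fh = RIGHT_EYE_FRACTIONS
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    ox = _round_half_up(box.x0 + fx * box.w)
    oy = _round_half_up(box.y0 + fy * box.h)
    pw = _round_half_up(fw * box.w)
    ph = _round_half_up(fh * box.h)

    x1, y1 = ox + pw, oy + ph
    cx0, cy0 = max(ox, 0), max(oy, 0)
    cx1, cy1 = min(x1, W), min(y1, H)
    if (cx0, cy0, cx1, cy1) != (ox, oy, x1, y1):
        logger.warning(
            "periocular crop clipped to source bounds: requested "
            "(%d,%d)-(%d,%d) in %dx%d image", ox, oy, x1, y1, W, H,
        )
        # clipping can leave an unusably thin sliver; unclipped crops keep
        # whatever size the percentages dictate (the processing stages have
        # their own size preconditions)
        if cx1 - cx0 < MIN_PATCH_SIZE or cy1 - cy0 < MIN_PATCH_SIZE:
            raise DegenerateInputError(
                f"clipped patch {cx1 - cx0}x{cy1 - cy0} is below the minimum "
                f"workable size {MIN_PATCH_SIZE}x{MIN_PATCH_SIZE}"
            )
    return PeriocularPatch(
        image=source[cy0:cy1, cx0:cx1].copy(),
        offset_x=cx0,
        offset_y=cy0,
        side=side,
    )


def patch_to_source(xy: tuple[float, float], patch: PeriocularPatch) -> tuple[float, float]:
    """Map a (x, y) coordinate inside the patch back to source coordinates."""
    return (xy[0] + patch.offset_x, xy[1] + patch.offset_y)


def read_face_boxes(path: str | Path) -> dict[str, FaceBox]:
    """Parse a face-box sidecar: one ``<image-name> <x0> <y0> <w> <h>`` per line."""
    boxes: dict[str, FaceBox] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected '<name> <x0> <y0> <w> <h>'")
        try:
            name, coords = parts[0], [int(p) for p in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer box coordinate") from exc
        boxes[name] = FaceBox(*coords)
    return boxes
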