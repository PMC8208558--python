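"""Shared raster types, color conversions, morphology and image/video I/O.

All rasters are numpy arrays on a unit intensity scale: RGB frames are
``(H, W, 3)`` floats in ``[0, 1]``, grayscale images ``(H, W)`` floats in
``[0, 1]`` and binary masks ``(H, W)`` booleans.  8-bit files are divided by
255 on read and multiplied back on write.  Coordinates are 0-based with the
origin at the top-left corner; ``x`` indexes columns and ``y`` rows, and
bounding boxes are ``(x, y, w, h)`` half-open pixel windows.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import exposure, morphology as skmorph
from skimage.color import rgb2lab

# Rec.601 luma weights (full precision, summing to exactly 1) -- the
# grayscale convention of mainstream image toolboxes, usually quoted
# rounded as 0.2989 / 0.5870 / 0.1140; the red-minus-gray detector branch
# depends on this convention.
REC601_WEIGHTS = np.array([0.298936021293775, 0.587043074451121, 0.114020904255104])


class ConfigError(ValueError):
    """Invalid parameter or configuration value."""


class ImageIOError(IOError):
    """File could not be read or written; message carries the path."""


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element for binary morphology.

    ``shape`` is either ``"square"`` (side = size) or ``"disk"``
    (diameter = size); ``size`` must be odd so the element has a center.
    """

    shape: str = "square"
    size: int = 3

    def __post_init__(self) -> None:
        if self.shape not in ("square", "disk"):
            raise ConfigError(f"unknown structuring element shape {self.shape!r}")
        if self.size < 1 or self.size % 2 == 0:
            raise ConfigError(f"structuring element size must be odd and >= 1, got {self.size}")

    def footprint(self) -> np.ndarray:
        if self.shape == "square":
            return skmorph.footprint_rectangle((self.size, self.size))
        return skmorph.disk(self.size // 2)


def as_frame(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a unit-scale RGB frame."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ConfigError(f"RGB frame must be (H, W, 3), got {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ConfigError("frame intensities must lie in [0, 1]")
    return arr


def to_gray(frame: np.ndarray, mode: str = "luminance") -> np.ndarray:
    """Convert an RGB frame to grayscale.

    ``luminance`` is the Rec.601 weighted sum 0.2989 R + 0.5870 G + 0.1140 B;
    ``lightness`` is the CIE-Lab L* channel rescaled from [0, 100] to [0, 1].
    """
    frame = np.asarray(frame, dtype=np.float64)
    if mode == "luminance":
        return frame @ REC601_WEIGHTS
    if mode == "lightness":
        return rgb2lab(frame)[..., 0] / 100.0
    raise ConfigError(f"unknown grayscale mode {mode!r}")


def binary_morphology(mask: np.ndarray, op: str, se: StructuringElement) -> np.ndarray:
    """Binary opening or closing with the given structuring element."""
    mask = np.asarray(mask, dtype=bool)
    if op not in ("open", "close"):
        raise ConfigError(f"unknown morphology op {op!r}")
    if se.shape == "square":
        # separable moving min/max: equivalent to erosion/dilation with a
        # square SE but O(N) in image size
        size = se.size
        if op == "open":
            eroded = ndimage.minimum_filter(mask, size=size, mode="constant", cval=False)
            return ndimage.maximum_filter(eroded, size=size, mode="constant", cval=False)
        pad = size
        padded = np.pad(mask, pad, mode="constant")
        dilated = ndimage.maximum_filter(padded, size=size, mode="constant", cval=False)
        closed = ndimage.minimum_filter(dilated, size=size, mode="constant", cval=False)
        return closed[pad:-pad, pad:-pad]
    fp = se.footprint().astype(bool)
    if op == "open":
        return ndimage.binary_opening(mask, structure=fp)
    # pad so dilation past the border is not clipped (closing must be
    # extensive, matching the set definition on the infinite plane)
    pad = se.size
    padded = np.pad(mask, pad, mode="constant")
    closed = ndimage.binary_closing(padded, structure=fp)
    return closed[pad:-pad, pad:-pad]


def clahe(
    img: np.ndarray,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a unit-scale image.

    ``tiles`` gives the (rows, cols) of the contextual tile grid; the kernel
    size passed to the underlying implementation is the image size divided by
    the grid.  Output is guaranteed to stay in [0, 1].
    """
    img = np.asarray(img)
    if clip_limit <= 0:
        raise ConfigError("clip_limit must be > 0")
    rows, cols = tiles
    if rows < 1 or cols < 1:
        raise ConfigError("tile grid must be at least (1, 1)")
    h, w = img.shape[:2]
    if h < rows or w < cols:
        raise ConfigError(f"image {img.shape} smaller than tile grid {tiles}")
    if np.ptp(img) == 0:
        # equalizing a constant image is a no-op by convention
        return img.astype(np.float64, copy=True)
    kernel = (max(1, h // rows), max(1, w // cols))
    out = exposure.equalize_adapthist(
        img.astype(np.float32), kernel_size=kernel, clip_limit=clip_limit
    )
    return np.clip(out.astype(np.float64), 0.0, 1.0)


# ---------------------------------------------------------------------------
# I/O


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask from a single-channel 0/255 PNG."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as a 0/255 single-channel PNG."""
    path = Path(path)
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    try:
        iio.imwrite(path, arr)
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot write mask {path}: {exc}") from exc


def _frame_to_uint8(frame: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(frame) * 255.0 + 0.5, 0, 255).astype(np.uint8)


_FRAME_RE = re.compile(r"(\d+)")


def _sorted_frame_files(directory: Path) -> list[Path]:
    files = [p for p in directory.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")]

    def key(p: Path):
        m = _FRAME_RE.findall(p.stem)
        return (int(m[-1]) if m else 0, p.name)

    return sorted(files, key=key)


def read_video(path: str | os.PathLike) -> Iterator[np.ndarray]:
    """Stream unit-scale RGB frames from a video file or image-sequence directory.

    A directory of numbered PNG/JPEG frames is accepted as an equivalent input
    to a video file; frames are ordered by the trailing number in their names.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such video or frame directory: {path}")
    if path.is_dir():
        files = _sorted_frame_files(path)
        if not files:
            raise ImageIOError(f"frame directory {path} contains no images")
        for f in files:
            arr = iio.imread(f)
            yield _normalize_decoded(arr)
        return
    try:
        for arr in iio.imiter(path):
            yield _normalize_decoded(arr)
    except (OSError, ValueError, ImportError) as exc:
        raise ImageIOError(f"cannot decode video {path}: {exc}") from exc


def _normalize_decoded(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_video(
    frames: Iterable[np.ndarray],
    path: str | os.PathLike,
    fps: float = 30.0,
) -> int:
    """Write frames to an image-sequence directory or a video file.

    Writing to a directory stores zero-padded ``frame_NNNNNN.png`` files and
    is always available; container formats (MP4/AVI) additionally require an
    ffmpeg-capable imageio backend.  Returns the number of frames written.
    """
    path = Path(path)
    if path.suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        n = 0
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", _frame_to_uint8(frame))
            n = i + 1
        return n
    try:
        buf = [_frame_to_uint8(f) for f in frames]
        iio.imwrite(path, np.stack(buf), fps=fps)
        return len(buf)
    except (OSError, ValueError, ImportError) as exc:
        raise ImageIOError(f"cannot encode video {path}: {exc}") from exc
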