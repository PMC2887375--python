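"""Reading, validation and windowing of grayscale image sequences.

An ultrasound loop is an ordered stack of equally sized grayscale B-mode
frames.  Every downstream step (wavelet feature tables, tracking) assumes the
frames are congruent in the raw sense — identical height and width — so this
module enforces that at load time and provides rectangular region-of-interest
cropping.

Coordinate convention, shared by the whole package: 0-based ``(row, col)``
with row increasing downward.  The row axis is the ultrasound depth axis, so
"transversal" displacement means displacement along rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageSequence",
    "RoiRect",
    "CongruenceError",
    "EmptySequenceError",
    "load_sequence",
    "save_sequence",
    "crop",
    "parse_roi",
]

_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


class CongruenceError(ValueError):
    """Frames (or coefficient layouts) that should be congruent are not."""


class EmptySequenceError(ValueError):
    """No frames found where a sequence was expected."""


@dataclass(frozen=True)
class RoiRect:
    """Rectangular region of interest, 0-based (row, col) top-left corner."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"ROI must have positive size, got {self.height}x{self.width}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.row0}, {self.col0})")


@dataclass
class ImageSequence:
    """Ordered stack of equally sized grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensities in [0, 1] (enforced).
    frame_rate : float, optional
        Frames per second.
    pixel_spacing : float or (float, float), optional
        Physical size of one pixel in mm, per axis (row, col).  A scalar is
        broadcast to both axes.
    """

    frames: np.ndarray
    frame_rate: float | None = None
    pixel_spacing: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n_frames, height, width), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise EmptySequenceError(f"a sequence needs at least 2 frames, got {self.frames.shape[0]}")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0.0 or hi > 1.0 + 1e-12:
            raise ValueError(f"intensities must lie in [0, 1] after normalization, got [{lo}, {hi}]")
        if self.frame_rate is not None and not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.pixel_spacing is not None:
            ps = np.atleast_1d(np.asarray(self.pixel_spacing, dtype=float))
            if ps.size == 1:
                ps = np.repeat(ps, 2)
            if ps.size != 2 or (ps <= 0).any():
                raise ValueError(f"pixel_spacing must be a positive scalar or pair, got {self.pixel_spacing}")
            self.pixel_spacing = (float(ps[0]), float(ps[1]))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray | None:
        """Frame acquisition times in seconds, if frame_rate is known."""
        if self.frame_rate is None:
            return None
        return np.arange(self.n_frames) / self.frame_rate


def _to_gray_unit(arr: np.ndarray, normalize: bool, origin: str) -> np.ndarray:
    """Convert one frame to float64 luminance in [0, 1]."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] == 3:
            from skimage.color import rgb2gray

            if np.issubdtype(arr.dtype, np.integer):
                info = np.iinfo(arr.dtype)
                arr = arr.astype(np.float64) / info.max
            return rgb2gray(arr)
        raise ValueError(f"{origin}: unsupported channel count {arr.shape[2]}")
    if arr.ndim != 2:
        raise ValueError(f"{origin}: expected 2-D frame, got ndim={arr.ndim}")
    if np.issubdtype(arr.dtype, np.integer):
        if normalize:
            info = np.iinfo(arr.dtype)
            return arr.astype(np.float64) / info.max
        return arr.astype(np.float64)
    return arr.astype(np.float64)


def load_sequence(
    path: str | Path,
    normalize: bool = True,
    frame_rate: float | None = None,
    pixel_spacing: float | tuple[float, float] | None = None,
) -> ImageSequence:
    """Load a grayscale image sequence.

    ``path`` is either a multi-page TIFF file or a directory of single-frame
    PNG/TIFF images taken in lexicographic filename order.  Integer inputs are
    scaled to [0, 1] by their dtype maximum (not the per-sequence maximum, so
    brightness changes between frames remain meaningful); color frames are
    converted to luminance.

    Raises
    ------
    EmptySequenceError
        If no frames are found.
    CongruenceError
        If frames differ in size; the message names the offending frame.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    names: list[str] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise EmptySequenceError(f"no image files found in directory {path}")
        import imageio.v3 as iio

        for f in files:
            frames.append(_to_gray_unit(iio.imread(f), normalize, f.name))
            names.append(f.name)
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        raw = tifffile.imread(path)
        raw = np.atleast_3d(raw)
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim == 3 and raw.shape[-1] in (3, 4) and raw.shape[0] not in (3, 4):
            raise ValueError(f"{path}: single color image is not a sequence")
        for i, page in enumerate(raw):
            frames.append(_to_gray_unit(page, normalize, f"page {i}"))
            names.append(f"page {i}")
    if not frames:
        raise EmptySequenceError(f"no frames read from {path}")
    shape0 = frames[0].shape
    for name, fr in zip(names, frames):
        if fr.shape != shape0:
            raise CongruenceError(
                f"frame {name!r} has shape {fr.shape}, expected {shape0}: frames are not congruent"
            )
    stack = np.stack(frames)
    if not normalize:
        # caller asserts data are already in [0, 1]
        stack = np.clip(stack, 0.0, 1.0)
    return ImageSequence(stack, frame_rate=frame_rate, pixel_spacing=pixel_spacing)


def save_sequence(seq: ImageSequence, path: str | Path, dtype: str = "float32") -> Path:
    """Write a sequence as a multi-page TIFF.

    ``dtype`` may be ``uint8``, ``uint16`` (intensities scaled by the dtype
    maximum, so integer data round-trip bit-exactly through
    :func:`load_sequence`) or ``float32``.
    """
    path = Path(path)
    if dtype in ("uint8", "uint16"):
        info = np.iinfo(dtype)
        data = np.round(seq.frames * info.max).astype(dtype)
    elif dtype == "float32":
        data = seq.frames.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def crop(seq: ImageSequence, roi: RoiRect) -> ImageSequence:
    """Restrict every frame to ``roi``; pixel values are untouched."""
    r1, c1 = roi.row0 + roi.height, roi.col0 + roi.width
    if r1 > seq.height or c1 > seq.width:
        raise ValueError(
            f"ROI (rows {roi.row0}:{r1}, cols {roi.col0}:{c1}) extends outside "
            f"frame bounds {seq.height}x{seq.width}"
        )
    return ImageSequence(
        seq.frames[:, roi.row0 : r1, roi.col0 : c1].copy(),
        frame_rate=seq.frame_rate,
        pixel_spacing=seq.pixel_spacing,
    )


def parse_roi(text: str) -> RoiRect:
    """Parse a ``"row0,col0,height,width"`` string into a :class:`RoiRect`."""
    parts = text.split(",")
    if len(parts) != 4:
        raise ValueError(f"ROI string must be 'row0,col0,height,width', got {text!r}")
    row0, col0, height, width = (int(p.strip()) for p in parts)
    return RoiRect(row0, col0, height, width)
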