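"""Stack I/O, projections, background removal and frame re-alignment.

The central idea of the method lives here: frames of a fixed scene are
combined pixelwise (minimum, maximum, median or mean) into a *still
background* containing only the motionless elements; removing that
background from each frame leaves the moving organisms on an almost
uniform dark field, where thresholding is easy and robust.

Conventions used throughout the package
---------------------------------------
* pixel coordinates are ``(row, col)``, 0-based, origin at the top-left;
* images are integer arrays in the stack's bit depth (8-bit by default)
  and stay integer through every step: the mean and median projections
  and the grayscale conversion round half up;
* RGB images are processed channelwise for projection and removal;
  segmentation always runs on a grayscale residual.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import StackIOError, ValidationError

__all__ = [
    "ImageStack",
    "BackgroundModel",
    "ResidualFrame",
    "load_stack",
    "to_grayscale",
    "project",
    "remove_background",
    "register_stack",
    "write_image",
]

PROJECTION_METHODS = ("min", "max", "median", "mean")
REMOVAL_MODES = ("subtract", "difference")

#: Rec.709 luminance weights for RGB -> grayscale.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves going up (0.5 -> 1), elementwise."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class ImageStack:
    """An ordered set of co-registered frames of one fixed scene.

    Parameters
    ----------
    frames : ndarray
        Shape ``(n, rows, cols)`` for grayscale or ``(n, rows, cols, 3)``
        for RGB; integer pixel values in ``[0, 2**bit_depth - 1]``.
    frame_index : tuple of int
        Strictly increasing index per frame (acquisition order).
    timestamps_s : tuple of float, optional
        Acquisition time of each frame in seconds.
    bit_depth : int
        Bits per channel; 8 by default.
    """

    frames: np.ndarray
    frame_index: tuple[int, ...]
    timestamps_s: tuple[float, ...] | None = None
    bit_depth: int = 8

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim not in (3, 4):
            raise ValidationError(
                f"frames must have shape (n, rows, cols[, 3]); got {frames.shape}"
            )
        if frames.ndim == 4 and frames.shape[-1] != 3:
            raise ValidationError(
                f"colour stacks must have 3 channels; got {frames.shape[-1]}"
            )
        if frames.shape[0] < 1:
            raise ValidationError("a stack needs at least one frame")
        if not np.issubdtype(frames.dtype, np.integer):
            raise ValidationError(f"pixel values must be integers, got {frames.dtype}")
        lo, hi = int(frames.min()), int(frames.max())
        limit = 2**self.bit_depth - 1
        if lo < 0 or hi > limit:
            raise ValidationError(
                f"pixel values [{lo}, {hi}] outside [0, {limit}] for "
                f"bit depth {self.bit_depth}"
            )
        idx = tuple(int(i) for i in self.frame_index)
        if len(idx) != frames.shape[0]:
            raise ValidationError("frame_index length must match the number of frames")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("frame_index must be strictly increasing")
        if self.timestamps_s is not None and len(self.timestamps_s) != len(idx):
            raise ValidationError("timestamps_s length must match the number of frames")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_index", idx)
        if self.timestamps_s is not None:
            object.__setattr__(
                self, "timestamps_s", tuple(float(t) for t in self.timestamps_s)
            )

    @classmethod
    def from_arrays(
        cls,
        frames: Sequence[np.ndarray] | np.ndarray,
        timestamps_s: Sequence[float] | None = None,
        bit_depth: int = 8,
    ) -> "ImageStack":
        """Build a stack from a list of equally-shaped frames, indexed 0..n-1."""
        arr = np.stack([np.asarray(f) for f in frames], axis=0)
        ts = tuple(timestamps_s) if timestamps_s is not None else None
        return cls(arr, tuple(range(arr.shape[0])), ts, bit_depth)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return self.frames.shape[1:]

    @property
    def is_rgb(self) -> bool:
        return self.frames.ndim == 4

    def __len__(self) -> int:
        return self.n_frames

    def subset(self, positions: Sequence[int]) -> "ImageStack":
        """Sub-stack at the given frame *positions* (kept in the given order)."""
        positions = list(positions)
        ts = (
            tuple(self.timestamps_s[p] for p in positions)
            if self.timestamps_s is not None
            else None
        )
        return ImageStack(
            self.frames[positions],
            tuple(self.frame_index[p] for p in positions),
            ts,
            self.bit_depth,
        )

    def prefix(self, n: int) -> "ImageStack":
        """The first ``n`` frames."""
        return self.subset(range(n))


@dataclass(frozen=True)
class BackgroundModel:
    """A per-pixel estimate of the still background.

    ``image`` has the shape and depth of the source frames; ``method`` is the
    projection statistic that produced it and ``source_frame_indices`` the
    frames it was built from.
    """

    image: np.ndarray
    method: str
    source_frame_indices: tuple[int, ...]


@dataclass(frozen=True)
class ResidualFrame:
    """One frame after background removal: non-zero only where something moved."""

    image: np.ndarray
    mode: str
    source_frame_index: int


def load_stack(paths: Sequence[str | os.PathLike]) -> ImageStack:
    """Read an ordered list of image files (or one multi-page TIFF) as a stack.

    File order is temporal order. All frames must share shape, channel count
    and dtype. RGB files keep their 3 channels; RGBA is not supported.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("load_stack needs at least one path")
    if len(paths) == 1 and paths[0].suffix.lower() in {".tif", ".tiff"}:
        try:
            arr = tifffile.imread(paths[0])
        except (OSError, ValueError) as exc:
            raise StackIOError(f"could not read {paths[0]}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        return ImageStack.from_arrays(arr)

    frames: list[np.ndarray] = []
    for p in paths:
        try:
            img = np.asarray(iio.imread(p))
        except (OSError, ValueError, RuntimeError) as exc:
            # imageio delegates to backend plugins whose failures surface
            # as RuntimeError as well as OSError
            raise StackIOError(f"could not read {p}: {exc}") from exc
        if img.ndim == 3 and img.shape[-1] == 4:  # drop alpha if fully opaque
            img = img[..., :3]
        frames.append(img)
        if img.shape != frames[0].shape:
            raise ValidationError(
                f"frame shape mismatch: {p} has shape {img.shape}, "
                f"expected {frames[0].shape} (from {paths[0]})"
            )
    return ImageStack.from_arrays(frames)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit image (grayscale or RGB) as PNG/TIFF/JPEG by extension."""
    path = Path(path)
    arr = np.asarray(image)
    if not np.issubdtype(arr.dtype, np.unsignedinteger):
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, arr)
        else:
            iio.imwrite(path, arr)
    except (OSError, ValueError) as exc:
        raise StackIOError(f"could not write {path}: {exc}") from exc


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to grayscale luminance (rounded half up).

    Grayscale input is returned unchanged. Uses Rec.709 weights
    0.2126 R + 0.7152 G + 0.0722 B.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 3:
        lum = _round_half_up(frame.astype(float) @ _LUMA)
        return np.clip(lum, 0, 255).astype(frame.dtype)
    raise ValidationError(
        f"expected a 2-D grayscale or (rows, cols, 3) RGB frame, got shape {frame.shape}"
    )


def grayscale_stack(stack: ImageStack) -> ImageStack:
    """Channel-collapse every frame of an RGB stack; no-op for grayscale."""
    if not stack.is_rgb:
        return stack
    gray = np.stack([to_grayscale(f) for f in stack.frames], axis=0)
    return replace(stack, frames=gray)


def project(stack: ImageStack, method: str = "min") -> BackgroundModel:
    """Z-project a stack into a still-background image.

    ``min`` keeps the darkest value seen at each pixel (the right choice when
    organisms are brighter than the substrate), ``max`` the brightest (dark
    organisms), ``median``/``mean`` are robust alternatives for heterogeneous
    picture quality or slowly varying lighting. RGB stacks are projected per
    channel. Median of an even frame count is the mean of the two central
    order statistics rounded half up; the mean also rounds half up, so the
    output stays in the input bit depth.
    """
    if method not in PROJECTION_METHODS:
        raise ValidationError(f"unknown projection method {method!r}")
    frames = stack.frames
    n = frames.shape[0]
    if method == "min":
        img = frames.min(axis=0)
    elif method == "max":
        img = frames.max(axis=0)
    elif method == "mean":
        s = frames.sum(axis=0, dtype=np.int64)
        img = ((2 * s + n) // (2 * n)).astype(frames.dtype)
    else:  # median
        srt = np.sort(frames, axis=0)
        if n % 2 == 1:
            img = srt[n // 2]
        else:
            a = srt[n // 2 - 1].astype(np.int64)
            b = srt[n // 2].astype(np.int64)
            img = ((a + b + 1) // 2).astype(frames.dtype)
    return BackgroundModel(img, method, stack.frame_index)


def remove_background(
    frame: np.ndarray,
    background: BackgroundModel | np.ndarray,
    mode: str = "subtract",
    frame_index: int = 0,
) -> ResidualFrame:
    """Remove the still background from one frame.

    ``subtract`` clips at zero (``max(frame - background, 0)``) and suits a
    min-projection background with bright organisms; ``difference`` takes the
    absolute difference and reveals organisms regardless of polarity. RGB is
    handled per channel.
    """
    if mode not in REMOVAL_MODES:
        raise ValidationError(f"unknown removal mode {mode!r}")
    bg = background.image if isinstance(background, BackgroundModel) else background
    frame = np.asarray(frame)
    bg = np.asarray(bg)
    if frame.shape != bg.shape:
        raise ValidationError(
            f"frame shape {frame.shape} does not match background shape {bg.shape}"
        )
    diff = frame.astype(np.int32) - bg.astype(np.int32)
    if mode == "subtract":
        res = np.clip(diff, 0, None)
    else:
        res = np.abs(diff)
    return ResidualFrame(res.astype(frame.dtype), mode, int(frame_index))


def _cross_correlation_shift(reference: np.ndarray, frame: np.ndarray) -> tuple[int, int]:
    """Integer translation to apply to ``frame`` so it best matches ``reference``.

    Computed as the argmax of the circular cross-correlation of the
    mean-subtracted images, evaluated via the product of their Fourier
    transforms.
    """
    ref = reference.astype(float)
    frm = frame.astype(float)
    ref -= ref.mean()
    frm -= frm.mean()
    corr = np.fft.irfft2(
        np.fft.rfft2(ref) * np.conj(np.fft.rfft2(frm)), s=ref.shape
    )
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = []
    for p, size in zip(peak, corr.shape):
        shift.append(int(p) if p <= size // 2 else int(p) - size)
    return (shift[0], shift[1])


def _apply_translation(
    frame: np.ndarray, shift: tuple[int, int], fill_from: np.ndarray
) -> np.ndarray:
    """Translate ``frame`` by ``shift`` (rows, cols); vacated margins are
    filled with the corresponding pixels of ``fill_from``."""
    out = fill_from.copy()
    dr, dc = shift
    rows, cols = frame.shape[:2]
    src_r = slice(max(0, -dr), rows - max(0, dr))
    src_c = slice(max(0, -dc), cols - max(0, dc))
    dst_r = slice(max(0, dr), rows - max(0, -dr))
    dst_c = slice(max(0, dc), cols - max(0, -dc))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def register_stack(
    stack: ImageStack, reference_index: int = 0
) -> tuple[ImageStack, list[tuple[int, int]]]:
    """Re-align a stack that drifted by pure translation.

    Each frame is shifted by the integer-pixel translation that maximises its
    cross-correlation with the reference frame (computed in the Fourier
    domain); margins vacated by the shift are filled with the reference
    frame's pixels. Returns the aligned stack and the per-frame
    ``(row, col)`` shifts that were applied.
    """
    if stack.n_frames < 2:
        raise ValidationError("registration needs at least 2 frames")
    if not (0 <= reference_index < stack.n_frames):
        raise ValidationError(
            f"reference_index {reference_index} out of range [0, {stack.n_frames})"
        )
    ref = stack.frames[reference_index]
    ref_gray = to_grayscale(ref) if stack.is_rgb else ref
    aligned = np.empty_like(stack.frames)
    shifts: list[tuple[int, int]] = []
    for i, frame in enumerate(stack.frames):
        if i == reference_index:
            shifts.append((0, 0))
            aligned[i] = frame
            continue
        gray = to_grayscale(frame) if stack.is_rgb else frame
        shift = _cross_correlation_shift(ref_gray, gray)
        shifts.append(shift)
        aligned[i] = _apply_translation(frame, shift, ref)
    return replace(stack, frames=aligned), shifts
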