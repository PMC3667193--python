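"""Thresholding residual frames, labelling particles and measuring them.

Once the still background has been removed, moving organisms sit on a
near-zero field, so a wide range of thresholds separates them cleanly.
This module turns a residual frame into a binary mask, labels maximal
connected foreground components ("particles"), and measures each one in
physical units via a pixels-per-millimetre calibration that can be read
off a reference square of known size placed in the scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from .errors import CalibrationError, DegenerateImageError, ValidationError
from .imaging import BackgroundModel, ResidualFrame, to_grayscale

__all__ = [
    "ScaleCalibration",
    "ParticleRecord",
    "BinaryMask",
    "otsu_threshold",
    "threshold_residual",
    "label_particles",
    "measure_particles",
    "filter_particles",
    "calibrate_scale",
    "particles_to_dataframe",
]

#: Column order of the particle CSV written by the batch runner.
PARTICLE_COLUMNS = [
    "label",
    "frame_index",
    "area_mm2",
    "length_mm",
    "centroid_row",
    "centroid_col",
    "bbox_min_row",
    "bbox_min_col",
    "bbox_max_row",
    "bbox_max_col",
    "mean_intensity",
    "mean_r",
    "mean_g",
    "mean_b",
]


@dataclass(frozen=True)
class ScaleCalibration:
    """Physical scale of the scene.

    ``pixels_per_mm`` converts pixel measurements to millimetres; ``source``
    records whether it was supplied manually or derived from a reference
    square in the frame.
    """

    pixels_per_mm: float
    source: str = "manual"

    def __post_init__(self) -> None:
        if not self.pixels_per_mm > 0:
            raise ValidationError("pixels_per_mm must be positive")


@dataclass(frozen=True)
class ParticleRecord:
    """One detected moving particle in one frame.

    ``length_mm`` is the major-axis length of the ellipse with the same
    second moments as the particle (the ImageJ "fit ellipse" convention);
    single-pixel particles are assigned a length of one pixel. ``bbox`` is
    half-open ``(min_row, min_col, max_row, max_col)``.
    """

    label: int
    frame_index: int
    area_mm2: float
    length_mm: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    mean_intensity: float
    area_px: int
    mean_colour: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class BinaryMask:
    """A thresholded residual: True = foreground (candidate organism pixels)."""

    pixels: np.ndarray
    threshold_used: int
    polarity: str


def otsu_threshold(image: np.ndarray, n_levels: int = 256) -> int:
    """Otsu's threshold: the grey level maximising between-class variance.

    The variance is evaluated for every candidate level ``t`` (class 0 =
    pixels ``<= t``, class 1 = pixels ``> t``). When several levels achieve
    the maximum — e.g. an image with only two grey values, where any cut
    between them is equally good — the middle of the optimal plateau is
    returned. A constant image has no two-class split and raises
    :class:`DegenerateImageError`.
    """
    image = np.asarray(image)
    hist = np.bincount(image.ravel().astype(np.int64), minlength=n_levels).astype(float)
    hist = hist[:n_levels]
    levels = np.arange(n_levels, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist)
    w1 = total - w0
    cum = np.cumsum(hist * levels)
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateImageError(
            "image is constant: no threshold separates two classes"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum / w0
        mu1 = (cum[-1] - cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    plateau = np.flatnonzero(sigma_b == sigma_b.max())
    return int(plateau[len(plateau) // 2])


def threshold_residual(
    residual: ResidualFrame | np.ndarray,
    method: str = "otsu",
    polarity: str = "bright",
    value: int | None = None,
) -> BinaryMask:
    """Binarise a grayscale residual frame.

    ``polarity="bright"`` selects pixels strictly above the threshold
    (organisms lighter than the substrate, residuals from a min-projection);
    ``"dark"`` selects pixels strictly below it. ``method="fixed"`` requires
    ``value``; ``"otsu"`` picks the threshold automatically from the
    histogram.
    """
    image = residual.image if isinstance(residual, ResidualFrame) else np.asarray(residual)
    if image.ndim != 2:
        raise ValidationError("thresholding requires a grayscale (2-D) residual")
    if polarity not in ("bright", "dark"):
        raise ValidationError(f"unknown polarity {polarity!r}")
    if method == "fixed":
        if value is None:
            raise ValidationError("method='fixed' requires a threshold value")
        t = int(value)
    elif method == "otsu":
        t = otsu_threshold(image)
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    fg = image > t if polarity == "bright" else image < t
    return BinaryMask(fg, t, polarity)


def label_particles(
    mask: BinaryMask | np.ndarray, connectivity: int = 8
) -> tuple[np.ndarray, int]:
    """Label maximal connected foreground components.

    ``connectivity=8`` joins diagonal neighbours (the particle-analyzer
    default); ``4`` joins edge neighbours only. Background pixels get label
    0; components get distinct labels 1..count.
    """
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    labels, count = _skmeasure.label(
        pixels.astype(bool), connectivity=1 if connectivity == 4 else 2, return_num=True
    )
    return labels, int(count)


def measure_particles(
    labels: np.ndarray,
    source_frame: np.ndarray,
    scale: ScaleCalibration,
    frame_index: int = 0,
    colour_frame: np.ndarray | None = None,
    length_metric: str = "ellipse",
) -> list[ParticleRecord]:
    """Measure every labelled particle in physical units.

    Area is the pixel count divided by ``pixels_per_mm**2``; length is the
    moment-ellipse major axis (or the maximum Feret diameter with
    ``length_metric="feret"``) divided by ``pixels_per_mm``. Mean intensity
    comes from ``source_frame``; if an RGB ``colour_frame`` is given the
    per-particle mean colour is retained as well.
    """
    if scale is None:
        raise ValidationError(
            "no scale calibration: supply pixels_per_mm manually or calibrate "
            "from a reference square (calibrate_scale)"
        )
    if length_metric not in ("ellipse", "feret"):
        raise ValidationError(f"unknown length metric {length_metric!r}")
    ppmm = scale.pixels_per_mm
    props = _skmeasure.regionprops(labels, intensity_image=np.asarray(source_frame))
    records: list[ParticleRecord] = []
    for p in props:
        if length_metric == "feret":
            length_px = p.feret_diameter_max
        else:
            length_px = p.axis_major_length
        length_px = max(float(length_px), 1.0)  # a single pixel spans one pixel
        colour = None
        if colour_frame is not None:
            rr, cc = p.coords[:, 0], p.coords[:, 1]
            pix = np.asarray(colour_frame)[rr, cc].astype(float)
            colour = tuple(float(v) for v in pix.mean(axis=0))
        records.append(
            ParticleRecord(
                label=int(p.label),
                frame_index=int(frame_index),
                area_mm2=float(p.area) / ppmm**2,
                length_mm=length_px / ppmm,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                bbox=tuple(int(v) for v in p.bbox),
                mean_intensity=float(p.intensity_mean),
                area_px=int(p.area),
                mean_colour=colour,
            )
        )
    return records


def filter_particles(
    records: Iterable[ParticleRecord],
    min_area_mm2: float = 0.0,
    max_area_mm2: float = math.inf,
    roi=None,
    exclude_edge: bool = False,
    frame_shape: tuple[int, int] | None = None,
) -> list[ParticleRecord]:
    """Keep particles within an area range and (optionally) inside an ROI.

    ROI membership is decided by the centroid. With ``exclude_edge`` set,
    particles whose bounding box touches the frame border are dropped
    (``frame_shape`` required). Input order is preserved.
    """
    if min_area_mm2 > max_area_mm2:
        raise ValidationError(
            f"min_area_mm2 ({min_area_mm2}) exceeds max_area_mm2 ({max_area_mm2})"
        )
    if exclude_edge and frame_shape is None:
        raise ValidationError("exclude_edge requires frame_shape")
    out = []
    for r in records:
        if not (min_area_mm2 <= r.area_mm2 <= max_area_mm2):
            continue
        if roi is not None and not roi.contains(*r.centroid):
            continue
        if exclude_edge:
            mr, mc, xr, xc = r.bbox
            if mr == 0 or mc == 0 or xr == frame_shape[0] or xc == frame_shape[1]:
                continue
        out.append(r)
    return out


def calibrate_scale(
    background: BackgroundModel | np.ndarray, reference_side_mm: float
) -> ScaleCalibration:
    """Derive pixels-per-mm from a dark reference square of known side length.

    The background image is Otsu-thresholded with dark polarity; the largest
    dark component is taken as the square and ``pixels_per_mm =
    sqrt(area_px) / reference_side_mm``. The component's bounding-box aspect
    ratio must lie in [0.8, 1.25], otherwise the calibration is rejected.
    """
    if not reference_side_mm > 0:
        raise ValidationError("reference_side_mm must be positive")
    img = background.image if isinstance(background, BackgroundModel) else background
    gray = to_grayscale(np.asarray(img))
    try:
        mask = threshold_residual(gray, method="otsu", polarity="dark")
    except DegenerateImageError as exc:
        raise CalibrationError(f"no dark reference found: {exc}") from exc
    labels, count = label_particles(mask)
    if count == 0:
        raise CalibrationError("no dark component found in the background image")
    props = _skmeasure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    mr, mc, xr, xc = largest.bbox
    h, w = xr - mr, xc - mc
    aspect = h / w
    if not (0.8 <= aspect <= 1.25):
        raise CalibrationError(
            f"largest dark component is not square-ish (aspect ratio {aspect:.2f})"
        )
    return ScaleCalibration(
        pixels_per_mm=math.sqrt(float(largest.area)) / reference_side_mm,
        source="reference_square",
    )


def particles_to_dataframe(records: Sequence[ParticleRecord]) -> pd.DataFrame:
    """Flatten particle records to a table with fixed, documented columns."""
    rows = []
    for r in records:
        colour = r.mean_colour if r.mean_colour is not None else (np.nan,) * 3
        rows.append(
            {
                "label": r.label,
                "frame_index": r.frame_index,
                "area_mm2": r.area_mm2,
                "length_mm": r.length_mm,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "bbox_min_row": r.bbox[0],
                "bbox_min_col": r.bbox[1],
                "bbox_max_row": r.bbox[2],
                "bbox_max_col": r.bbox[3],
                "mean_intensity": r.mean_intensity,
                "mean_r": colour[0],
                "mean_g": colour[1],
                "mean_b": colour[2],
            }
        )
    return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)
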