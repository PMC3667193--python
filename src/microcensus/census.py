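"""Per-box population census.

Chains the imaging and segmentation primitives into the standard per-box
pipeline — optional re-alignment, grayscale conversion, Z-projection,
background removal, thresholding, labelling, measurement, filtering —
and aggregates the result into per-frame counts, total biosurface
(summed particle area, a biomass proxy), and a fixed-bin size
distribution. Also provides the arena (ROI) auto-detector, the
stack-size reliability experiment, and the biosurface-regression density
correction that de-biases counts at high density, where touching
organisms merge into single particles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy import stats as _stats
from skimage import measure as _skmeasure

from .errors import DegenerateImageError, RoiDetectionError, ValidationError
from .imaging import (
    BackgroundModel,
    ImageStack,
    grayscale_stack,
    project,
    register_stack,
    remove_background,
    to_grayscale,
)
from .segmentation import (
    ParticleRecord,
    ScaleCalibration,
    calibrate_scale,
    filter_particles,
    label_particles,
    measure_particles,
    threshold_residual,
)

__all__ = [
    "RegionOfInterest",
    "CensusConfig",
    "CensusResult",
    "SizeHistogram",
    "DensityCalibration",
    "detect_roi",
    "census_box",
    "size_distribution",
    "fit_density_calibration",
    "correct_density",
    "reliability_curve",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """The arena sub-area within which particles are counted.

    ``shape`` is one of ``rectangle`` (params ``(min_row, min_col, max_row,
    max_col)``, half-open), ``disk`` (``(center_row, center_col, radius)``)
    or ``polygon`` (``((r0, c0), (r1, c1), ...)``).
    """

    shape: str
    params: tuple

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "disk", "polygon"):
            raise ValidationError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "rectangle":
            mr, mc, xr, xc = self.params
            if not (xr > mr and xc > mc):
                raise ValidationError(f"empty rectangle ROI {self.params}")
        elif self.shape == "disk":
            if not self.params[2] > 0:
                raise ValidationError("disk ROI needs a positive radius")
        else:
            if len(self.params) < 3:
                raise ValidationError("polygon ROI needs at least 3 vertices")

    @classmethod
    def rectangle(cls, min_row, min_col, max_row, max_col) -> "RegionOfInterest":
        return cls("rectangle", (float(min_row), float(min_col), float(max_row), float(max_col)))

    @classmethod
    def disk(cls, center_row, center_col, radius) -> "RegionOfInterest":
        return cls("disk", (float(center_row), float(center_col), float(radius)))

    @classmethod
    def polygon(cls, vertices: Sequence[tuple[float, float]]) -> "RegionOfInterest":
        return cls("polygon", tuple((float(r), float(c)) for r, c in vertices))

    def contains(self, row: float, col: float) -> bool:
        """Whether a (row, col) point lies inside the region."""
        if self.shape == "rectangle":
            mr, mc, xr, xc = self.params
            return mr <= row < xr and mc <= col < xc
        if self.shape == "disk":
            cr, cc, rad = self.params
            return (row - cr) ** 2 + (col - cc) ** 2 <= rad**2
        return bool(_MplPath(np.asarray(self.params)).contains_point((row, col)))


@dataclass(frozen=True)
class SizeHistogram:
    """Fixed-bin size distribution with explicit out-of-range tallies.

    Bins are left-closed ``[edge, edge + width)``; the last bin also includes
    its right edge. Particles outside ``[bin_edges[0], bin_edges[-1]]`` are
    counted in ``underflow``/``overflow``, never in the bins.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    underflow: int = 0
    overflow: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_left_edge_mm": self.bin_edges[:-1], "count": self.counts}
        )


@dataclass(frozen=True)
class CensusConfig:
    """All tunable parameters of the per-box pipeline.

    Defaults match the core rearing-box workflow: bright organisms on a
    darkened substrate, min-projection background, subtract-mode removal,
    automatic (Otsu) thresholding, 8-connectivity, no size gate, full-frame
    ROI, manual scale.
    """

    projection: str = "min"
    removal_mode: str = "subtract"
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    threshold_value: int | None = None
    polarity: str = "bright"
    connectivity: int = 8
    min_area_mm2: float = 0.0
    max_area_mm2: float = math.inf
    roi_mode: str = "full-frame"  # "full-frame" | "auto" | "manual"
    roi: RegionOfInterest | None = None
    roi_polarity: str = "dark"
    roi_margin_frac: float = 0.02
    scale_mode: str = "manual"  # "manual" | "reference_square"
    pixels_per_mm: float = 1.0
    reference_side_mm: float | None = None
    register: bool = False
    register_reference: int = 0
    exclude_edge_particles: bool = False
    length_metric: str = "ellipse"
    hist_min_mm: float = 0.1
    hist_max_mm: float = 3.0
    hist_bin_width_mm: float = 0.02
    aggregate: str = "mean"  # "mean" | "median"
    sliding_window: int | None = None
    sliding_method: str = "min"

    def __post_init__(self) -> None:
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValidationError("threshold_method='fixed' requires threshold_value")
        if self.roi_mode == "manual" and self.roi is None:
            raise ValidationError("roi_mode='manual' requires an roi")
        if self.scale_mode == "reference_square" and self.reference_side_mm is None:
            raise ValidationError(
                "scale_mode='reference_square' requires reference_side_mm"
            )
        if self.aggregate not in ("mean", "median"):
            raise ValidationError(f"unknown aggregate {self.aggregate!r}")


@dataclass(frozen=True)
class CensusResult:
    """Summary of one box: counts, biosurface, size structure.

    ``biosurface_mm2`` is the mean over frames of the summed areas of the
    retained particles. ``corrected_count`` is only present after applying a
    :class:`DensityCalibration`; the raw counts are always retained.
    """

    per_frame_counts: tuple[int, ...]
    mean_count: float
    biosurface_mm2: float
    size_histogram: SizeHistogram
    n_frames_used: int
    particles: tuple[ParticleRecord, ...] = ()
    corrected_count: float | None = None
    background: BackgroundModel | None = None
    roi: RegionOfInterest | None = None
    scale: ScaleCalibration | None = None

    def summary_row(self) -> dict:
        return {
            "n_frames_used": self.n_frames_used,
            "mean_count": self.mean_count,
            "biosurface_mm2": self.biosurface_mm2,
            "corrected_count": self.corrected_count,
            "n_particles_measured": len(self.particles),
        }


@dataclass(frozen=True)
class DensityCalibration:
    """Linear map biosurface -> organism count, fitted at low density."""

    slope: float
    intercept: float
    fitted_on: tuple[tuple[float, float], ...]


def detect_roi(
    background: BackgroundModel | np.ndarray,
    polarity: str = "dark",
    margin_frac: float = 0.02,
) -> RegionOfInterest:
    """Auto-detect the arena as the largest dark (or bright) region.

    The background image is Otsu-thresholded; the bounding rectangle of the
    largest connected component, shrunk inward by ``margin_frac`` of its
    width on every side (to exclude the box wall), becomes the ROI. Fails if
    the component covers less than 10% of the frame.
    """
    img = background.image if isinstance(background, BackgroundModel) else background
    gray = to_grayscale(np.asarray(img))
    try:
        mask = threshold_residual(gray, method="otsu", polarity=polarity)
    except DegenerateImageError as exc:
        raise RoiDetectionError(
            f"arena detection failed ({exc}); supply a manual ROI"
        ) from exc
    labels, count = label_particles(mask)
    if count == 0:
        raise RoiDetectionError("no candidate arena component; supply a manual ROI")
    props = _skmeasure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    if largest.area < 0.1 * gray.size:
        raise RoiDetectionError(
            f"largest component covers only {largest.area / gray.size:.1%} of the "
            "frame (<10%); supply a manual ROI"
        )
    mr, mc, xr, xc = largest.bbox
    margin = int(round(margin_frac * (xc - mc)))
    mr, mc, xr, xc = mr + margin, mc + margin, xr - margin, xc - margin
    if not (xr > mr and xc > mc):
        raise RoiDetectionError("detected arena collapsed after margin shrink")
    return RegionOfInterest.rectangle(mr, mc, xr, xc)


def _threshold_safe(residual, config: CensusConfig):
    """Threshold a residual; a contrast-free (constant) residual yields an
    empty mask instead of an error, so organism-free frames count zero."""
    try:
        return threshold_residual(
            residual,
            method=config.threshold_method,
            polarity=config.polarity,
            value=config.threshold_value,
        )
    except DegenerateImageError:
        img = residual.image
        from .segmentation import BinaryMask

        return BinaryMask(np.zeros(img.shape, dtype=bool), 0, config.polarity)


def census_box(stack: ImageStack, config: CensusConfig = CensusConfig()) -> CensusResult:
    """Run the full census pipeline on one box's stack.

    Deterministic given the stack and config. Frames are optionally
    re-aligned, converted to grayscale, projected into a background, and each
    frame's residual is thresholded, labelled, measured and filtered; counts
    and biosurface are aggregated over frames and all retained particles are
    pooled into the size histogram.
    """
    if stack.n_frames < 2:
        warnings.warn(
            "census on fewer than 2 frames: no motion signal, the background "
            "equals the frame and nothing can be detected",
            stacklevel=2,
        )
    work = stack
    if config.register and work.n_frames >= 2:
        work, _ = register_stack(work, config.register_reference)
    colour_frames = work.frames if work.is_rgb else None
    gray = grayscale_stack(work)
    background = project(gray, config.projection)

    if config.scale_mode == "reference_square":
        scale = calibrate_scale(background, config.reference_side_mm)
    else:
        scale = ScaleCalibration(config.pixels_per_mm, source="manual")

    if config.roi_mode == "auto":
        roi = detect_roi(background, config.roi_polarity, config.roi_margin_frac)
    elif config.roi_mode == "manual":
        roi = config.roi
    else:
        roi = None

    backgrounds = None
    if config.sliding_window is not None:
        from .tracking import sliding_background

        backgrounds = sliding_background(gray, config.sliding_window, config.sliding_method)

    per_frame_counts: list[int] = []
    per_frame_area: list[float] = []
    all_particles: list[ParticleRecord] = []
    for pos in range(gray.n_frames):
        frame = gray.frames[pos]
        bg = backgrounds[pos] if backgrounds is not None else background
        try:
            residual = remove_background(
                frame, bg, config.removal_mode, gray.frame_index[pos]
            )
            mask = _threshold_safe(residual, config)
            labels, _ = label_particles(mask, config.connectivity)
            records = measure_particles(
                labels,
                frame,
                scale,
                frame_index=gray.frame_index[pos],
                colour_frame=colour_frames[pos] if colour_frames is not None else None,
                length_metric=config.length_metric,
            )
            records = filter_particles(
                records,
                config.min_area_mm2,
                config.max_area_mm2,
                roi=roi,
                exclude_edge=config.exclude_edge_particles,
                frame_shape=frame.shape,
            )
        except (ValidationError, DegenerateImageError) as exc:
            raise type(exc)(f"frame {gray.frame_index[pos]}: {exc}") from exc
        per_frame_counts.append(len(records))
        per_frame_area.append(sum(r.area_mm2 for r in records))
        all_particles.extend(records)

    agg = np.mean if config.aggregate == "mean" else np.median
    hist = size_distribution(
        all_particles,
        config.hist_min_mm,
        config.hist_max_mm,
        config.hist_bin_width_mm,
    )
    return CensusResult(
        per_frame_counts=tuple(per_frame_counts),
        mean_count=float(agg(per_frame_counts)) if per_frame_counts else 0.0,
        biosurface_mm2=float(np.mean(per_frame_area)) if per_frame_area else 0.0,
        size_histogram=hist,
        n_frames_used=gray.n_frames,
        particles=tuple(all_particles),
        background=background,
        roi=roi,
        scale=scale,
    )


def size_distribution(
    records: Iterable[ParticleRecord] | Sequence[float],
    min_mm: float = 0.1,
    max_mm: float = 3.0,
    bin_width_mm: float = 0.02,
) -> SizeHistogram:
    """Bin particle lengths into fixed classes.

    The defaults split [0.1, 3.0] mm into 145 classes of 0.02 mm. Bins are
    left-closed; the last bin is closed on both sides; lengths outside the
    range land in the underflow/overflow tallies. The width must divide the
    range to within 1e-9; bin assignment tolerates 1e-9 mm of floating-point
    slack at the edges.
    """
    if not bin_width_mm > 0:
        raise ValidationError("bin width must be positive")
    if not max_mm > min_mm:
        raise ValidationError("max_mm must exceed min_mm")
    n_bins = round((max_mm - min_mm) / bin_width_mm)
    if n_bins < 1 or abs(n_bins * bin_width_mm - (max_mm - min_mm)) > 1e-9:
        raise ValidationError(
            f"bin width {bin_width_mm} does not divide the range "
            f"[{min_mm}, {max_mm}]"
        )
    lengths = np.asarray(
        [r.length_mm if isinstance(r, ParticleRecord) else float(r) for r in records],
        dtype=float,
    )
    edges = min_mm + np.arange(n_bins + 1) * bin_width_mm
    counts = np.zeros(n_bins, dtype=int)
    under = over = 0
    eps = 1e-9
    for length in lengths:
        if length < min_mm - eps:
            under += 1
        elif length > max_mm + eps:
            over += 1
        else:
            idx = int(math.floor((length - min_mm) / bin_width_mm + eps))
            counts[min(idx, n_bins - 1)] += 1
    return SizeHistogram(edges, counts, under, over)


def fit_density_calibration(
    pairs: Sequence[tuple[float, float]]
) -> DensityCalibration:
    """Ordinary least squares of manual count on biosurface.

    Fitted on low-density boxes, where the automatic count is unbiased, so
    the line can later convert biosurface into a count at densities where
    merging makes raw counts unreliable.
    """
    pairs = [(float(b), float(c)) for b, c in pairs]
    if len(pairs) < 2:
        raise ValidationError("need at least 2 (biosurface, count) pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValidationError("all biosurfaces identical: regression is degenerate")
    fit = _stats.linregress(x, y)
    return DensityCalibration(float(fit.slope), float(fit.intercept), tuple(pairs))


def correct_density(result: CensusResult, calib: DensityCalibration) -> CensusResult:
    """Attach the regression-corrected count (floored at 0) to a census result.

    The raw per-frame counts and mean count are kept unchanged; correction is
    meant for high densities where touching organisms merge and the raw count
    undershoots.
    """
    corrected = max(calib.slope * result.biosurface_mm2 + calib.intercept, 0.0)
    return replace(result, corrected_count=float(corrected))


def reliability_curve(
    stack: ImageStack,
    config: CensusConfig = CensusConfig(),
    n_values: Sequence[int] = (2, 3, 4, 5),
    random_subsets: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Biosurface as a function of the number of pictures in the stack.

    For each ``n`` the census (background included) is recomputed from the
    first ``n`` frames; with ``random_subsets=R`` and a seed, ``R`` random
    ``n``-frame subsets (in temporal order) are added. Returns a DataFrame
    with columns ``n``, ``subset`` (``"prefix"`` or ``"random<k>"``) and
    ``biosurface_mm2``.
    """
    n_values = [int(n) for n in n_values]
    if max(n_values) > stack.n_frames:
        raise ValidationError(
            f"n_values up to {max(n_values)} exceed the stack size {stack.n_frames}"
        )
    if random_subsets > 0 and seed is None:
        raise ValidationError("random subsets require an explicit seed")
    rng = np.random.default_rng(seed) if random_subsets > 0 else None
    rows = []
    for n in n_values:
        if n < 2:
            warnings.warn(f"n={n}: no motion signal, biosurface will be 0", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = census_box(stack.prefix(n), config)
        rows.append({"n": n, "subset": "prefix", "biosurface_mm2": res.biosurface_mm2})
        for k in range(random_subsets):
            pos = np.sort(rng.choice(stack.n_frames, size=n, replace=False))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = census_box(stack.subset(pos), config)
            rows.append(
                {"n": n, "subset": f"random{k}", "biosurface_mm2": res.biosurface_mm2}
            )
    return pd.DataFrame(rows, columns=["n", "subset", "biosurface_mm2"])
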