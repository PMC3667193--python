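"""Long time-lapse applications: sliding backgrounds, trajectories, activity.

Over hours the scene slowly stops being "fixed" (substrate drying, light
drift), so a single global background blurs. The fix is to rebuild the
background on a sliding window of frames around each time point. On top
of that sit two applications: extracting the trajectory of a single
animal wandering in an arena, and counting the active animals inside an
ROI frame by frame to produce an activity time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CensusConfig, RegionOfInterest, _threshold_safe
from .errors import ValidationError
from .imaging import (
    BackgroundModel,
    ImageStack,
    grayscale_stack,
    project,
    remove_background,
)
from .segmentation import ScaleCalibration, filter_particles, label_particles, measure_particles

__all__ = [
    "Trajectory",
    "ActivitySeries",
    "sliding_background",
    "track_single",
    "activity_series",
    "block_mean",
]


@dataclass(frozen=True)
class Trajectory:
    """An ordered single-animal track.

    ``points`` are ``(frame_index, row, col)`` detections; ``gaps`` are the
    frame indices with no detection. Together they cover every processed
    frame; gap frames are reported, never interpolated.
    """

    points: tuple[tuple[int, float, float], ...]
    gaps: tuple[int, ...]

    @property
    def n_frames(self) -> int:
        return len(self.points) + len(self.gaps)

    def to_dataframe(self, scale: ScaleCalibration | None = None,
                     timestamps: dict[int, float] | None = None) -> pd.DataFrame:
        rows = []
        for idx, r, c in self.points:
            row = {
                "frame": idx,
                "t_seconds": timestamps.get(idx) if timestamps else float(idx),
                "row_px": r,
                "col_px": c,
            }
            if scale is not None:
                row["row_mm"] = r / scale.pixels_per_mm
                row["col_mm"] = c / scale.pixels_per_mm
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActivitySeries:
    """Counts of active (moving) animals per frame inside an ROI."""

    entries: tuple[tuple[float, int], ...]  # (timestamp_seconds, active_count)
    window_size: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["t_seconds", "count"])


def sliding_background(
    stack: ImageStack, window: int, method: str = "min"
) -> list[BackgroundModel]:
    """One background per frame, projected from a window centred on it.

    The window keeps its full length everywhere: near the stack ends it
    slides rather than shrinks, so every model is built from exactly
    ``window`` frames (constant estimator quality). ``window`` equal to the
    stack size reproduces the global projection for every frame.
    """
    if window < 2:
        raise ValidationError("sliding window must be >= 2")
    if window > stack.n_frames:
        raise ValidationError(
            f"window {window} exceeds stack size {stack.n_frames}"
        )
    models = []
    for i in range(stack.n_frames):
        lo = min(max(0, i - window // 2), stack.n_frames - window)
        models.append(project(stack.subset(range(lo, lo + window)), method))
    return models


def _detect_frame(gray_stack: ImageStack, pos: int, background, config: CensusConfig,
                  scale: ScaleCalibration, roi: RegionOfInterest | None):
    """Shared per-frame detection used by tracking and activity counting."""
    frame = gray_stack.frames[pos]
    residual = remove_background(
        frame, background, config.removal_mode, gray_stack.frame_index[pos]
    )
    mask = _threshold_safe(residual, config)
    labels, _ = label_particles(mask, config.connectivity)
    records = measure_particles(
        labels, frame, scale,
        frame_index=gray_stack.frame_index[pos],
        length_metric=config.length_metric,
    )
    return filter_particles(
        records,
        config.min_area_mm2,
        config.max_area_mm2,
        roi=roi,
        exclude_edge=config.exclude_edge_particles,
        frame_shape=frame.shape,
    )


def _backgrounds_for(gray: ImageStack, config: CensusConfig):
    if config.sliding_window is not None:
        return sliding_background(gray, config.sliding_window, config.sliding_method)
    return [project(gray, config.projection)] * gray.n_frames


def track_single(stack: ImageStack, config: CensusConfig = CensusConfig()) -> Trajectory:
    """Extract the trajectory of (at most) one animal.

    Per frame, detection runs against the configured global or sliding
    background; the centroid of the *largest* retained particle is the
    position. Frames with no particle above the size gate are recorded as
    gaps. An empty trajectory is allowed.
    """
    gray = grayscale_stack(stack)
    scale = ScaleCalibration(config.pixels_per_mm, "manual")
    backgrounds = _backgrounds_for(gray, config)
    points: list[tuple[int, float, float]] = []
    gaps: list[int] = []
    for pos in range(gray.n_frames):
        records = _detect_frame(gray, pos, backgrounds[pos], config, scale, None)
        if records:
            best = max(records, key=lambda r: r.area_mm2)
            points.append((gray.frame_index[pos], best.centroid[0], best.centroid[1]))
        else:
            gaps.append(gray.frame_index[pos])
    return Trajectory(tuple(points), tuple(gaps))


def activity_series(
    stack: ImageStack,
    roi: RegionOfInterest | None,
    config: CensusConfig = CensusConfig(),
) -> ActivitySeries:
    """Count moving animals inside an ROI, frame by frame.

    Timestamps come from the stack if present, else the frame index is used
    as the time axis. The background is global or sliding per the config.
    """
    gray = grayscale_stack(stack)
    scale = ScaleCalibration(config.pixels_per_mm, "manual")
    backgrounds = _backgrounds_for(gray, config)
    entries = []
    for pos in range(gray.n_frames):
        records = _detect_frame(gray, pos, backgrounds[pos], config, scale, roi)
        t = (
            gray.timestamps_s[pos]
            if gray.timestamps_s is not None
            else float(gray.frame_index[pos])
        )
        entries.append((t, len(records)))
    window = config.sliding_window if config.sliding_window is not None else gray.n_frames
    return ActivitySeries(tuple(entries), window)


def block_mean(series: ActivitySeries, block: int) -> pd.DataFrame:
    """Block-average an activity series for presentation.

    Consecutive blocks of ``block`` entries are reduced to their mean time
    and mean count; a trailing partial block is averaged as-is. ``block=1``
    returns the series unchanged.
    """
    if block < 1:
        raise ValidationError("block length must be >= 1")
    t = np.array([e[0] for e in series.entries], dtype=float)
    c = np.array([e[1] for e in series.entries], dtype=float)
    rows = []
    for start in range(0, len(t), block):
        rows.append(
            {"t_seconds": t[start : start + block].mean(),
             "mean_count": c[start : start + block].mean()}
        )
    return pd.DataFrame(rows, columns=["t_seconds", "mean_count"])
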