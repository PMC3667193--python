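"""Recursive batch census over a directory tree of replicated microcosms.

One leaf directory = one box; its image files, in lexicographic order,
form the stack. The whole batch runs from a single config (YAML
key-value file or :class:`BatchConfig`); one box failing never aborts
the rest; outputs (summary table, per-box particle and histogram CSVs,
background images, provenance record) are written atomically, so
re-running on identical inputs reproduces them bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .census import CensusConfig, CensusResult, RegionOfInterest, census_box
from .errors import MicrocensusError, StackIOError, ValidationError
from .imaging import load_stack, write_image
from .segmentation import particles_to_dataframe

__all__ = ["BatchConfig", "BatchResult", "discover_boxes", "run_batch"]

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

logger = logging.getLogger("microcensus.batch")


@dataclass(frozen=True)
class BatchConfig:
    """Configuration of a batch run; every pipeline knob has a config key.

    ``roi`` (for ``roi_mode="manual"``) is ``(min_row, min_col, max_row,
    max_col)``. ``max_area_mm2`` may be the string ``"inf"`` in YAML.
    """

    root_dir: str
    output_dir: str
    projection: str = "min"
    removal_mode: str = "subtract"
    threshold_method: str = "otsu"
    threshold_value: int | None = None
    polarity: str = "bright"
    connectivity: int = 8
    min_area_mm2: float = 0.0
    max_area_mm2: float = math.inf
    roi_mode: str = "full-frame"
    roi: tuple[float, float, float, float] | None = None
    roi_polarity: str = "dark"
    roi_margin_frac: float = 0.02
    scale_mode: str = "manual"
    pixels_per_mm: float = 1.0
    reference_side_mm: float | None = None
    register: bool = False
    exclude_edge_particles: bool = False
    length_metric: str = "ellipse"
    hist_min_mm: float = 0.1
    hist_max_mm: float = 3.0
    hist_bin_width_mm: float = 0.02
    aggregate: str = "mean"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BatchConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("max_area_mm2"), str):
            raw["max_area_mm2"] = float(raw["max_area_mm2"])
        if raw.get("roi") is not None:
            raw["roi"] = tuple(raw["roi"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["max_area_mm2"] == math.inf:
            d["max_area_mm2"] = "inf"
        if d["roi"] is not None:
            d["roi"] = list(d["roi"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def census_config(self) -> CensusConfig:
        roi = RegionOfInterest.rectangle(*self.roi) if self.roi is not None else None
        return CensusConfig(
            projection=self.projection,
            removal_mode=self.removal_mode,
            threshold_method=self.threshold_method,
            threshold_value=self.threshold_value,
            polarity=self.polarity,
            connectivity=self.connectivity,
            min_area_mm2=self.min_area_mm2,
            max_area_mm2=self.max_area_mm2,
            roi_mode=self.roi_mode,
            roi=roi,
            roi_polarity=self.roi_polarity,
            roi_margin_frac=self.roi_margin_frac,
            scale_mode=self.scale_mode,
            pixels_per_mm=self.pixels_per_mm,
            reference_side_mm=self.reference_side_mm,
            register=self.register,
            exclude_edge_particles=self.exclude_edge_particles,
            length_metric=self.length_metric,
            hist_min_mm=self.hist_min_mm,
            hist_max_mm=self.hist_max_mm,
            hist_bin_width_mm=self.hist_bin_width_mm,
            aggregate=self.aggregate,
        )


@dataclass(frozen=True)
class BatchResult:
    """Everything a batch run produced.

    Every discovered box appears exactly once, either in ``results`` or in
    ``failures``.
    """

    results: dict[str, CensusResult]
    failures: tuple[tuple[str, str], ...]
    summary: pd.DataFrame
    provenance: dict

    @property
    def n_boxes(self) -> int:
        return len(self.results) + len(self.failures)


def discover_boxes(root_dir: str | Path) -> list[tuple[str, list[Path]]]:
    """Find boxes: leaf directories (no subdirectories) with >= 1 image file.

    Returns ``(box_id, ordered frame paths)`` with box ids (paths relative to
    the root) sorted and frames in lexicographic order.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise ValidationError(f"root directory {root} does not exist")
    boxes = []
    for dirpath, dirnames, filenames in os.walk(root):
        if dirnames:
            continue
        images = sorted(
            Path(dirpath) / f
            for f in filenames
            if Path(f).suffix.lower() in IMAGE_EXTENSIONS
        )
        if images:
            box_id = str(Path(dirpath).relative_to(root)) or "."
            boxes.append((box_id, images))
    if not boxes:
        raise ValidationError(f"no boxes (leaf directories with images) under {root}")
    return sorted(boxes, key=lambda b: b[0])


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_box_outputs(out_dir: Path, box_id: str, result: CensusResult) -> None:
    box_dir = out_dir / "boxes" / box_id
    box_dir.mkdir(parents=True, exist_ok=True)
    _atomic_write_text(
        box_dir / "particles.csv",
        particles_to_dataframe(result.particles).to_csv(index=False),
    )
    _atomic_write_text(
        box_dir / "histogram.csv", result.size_histogram.to_dataframe().to_csv(index=False)
    )
    if result.background is not None:
        write_image(result.background.image, box_dir / "background.png")


def run_batch(config: BatchConfig) -> BatchResult:
    """Census every box under ``config.root_dir``; never abort on one failure.

    Writes ``summary.csv``, per-box outputs and ``provenance.json`` under
    ``config.output_dir`` plus a run log; outputs are deterministic functions
    of inputs and config. Returns the in-memory :class:`BatchResult`.
    """
    out_dir = Path(config.output_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise StackIOError(f"output directory {out_dir} is not writable: {exc}") from exc

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        cfg_hash = config.config_hash()
        logger.info("batch start: root=%s config_hash=%s", config.root_dir, cfg_hash)
        boxes = discover_boxes(config.root_dir)
        census_cfg = config.census_config()

        results: dict[str, CensusResult] = {}
        failures: list[tuple[str, str]] = []
        rows = []
        frame_lists: dict[str, list[str]] = {}
        for box_id, paths in boxes:
            frame_lists[box_id] = [p.name for p in paths]
            try:
                stack = load_stack(paths)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = census_box(stack, census_cfg)
            except (MicrocensusError, OSError, ValueError) as exc:
                logger.error("box %s failed: %s", box_id, exc)
                failures.append((box_id, str(exc)))
                continue
            results[box_id] = result
            _write_box_outputs(out_dir, box_id, result)
            rows.append({"box_id": box_id, **result.summary_row()})
            logger.info(
                "box %s: mean_count=%.2f biosurface=%.3f mm^2",
                box_id, result.mean_count, result.biosurface_mm2,
            )

        summary = pd.DataFrame(
            rows,
            columns=[
                "box_id", "n_frames_used", "mean_count", "biosurface_mm2",
                "corrected_count", "n_particles_measured",
            ],
        )
        _atomic_write_text(out_dir / "summary.csv", summary.to_csv(index=False))
        provenance = {
            "config": config.to_dict(),
            "config_hash": cfg_hash,
            "software": {"name": "microcensus", "version": __version__},
            "boxes": frame_lists,
            "failures": [list(f) for f in failures],
        }
        _atomic_write_text(
            out_dir / "provenance.json",
            json.dumps(provenance, sort_keys=True, indent=1),
        )
        logger.info(
            "batch done: %d boxes, %d failures", len(boxes), len(failures)
        )
        return BatchResult(results, tuple(failures), summary, provenance)
    finally:
        logger.removeHandler(handler)
        handler.close()
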