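"""Seeded generator of microcosm image stacks with known ground truth.

Emulates the statistical structure of real rearing-box pictures: a
static, spatially heterogeneous substrate (smooth gradient, speckle
texture, a few fixed bright debris particles), N elliptical organisms
brighter (or darker) than the substrate performing independent random
walks, i.i.d. Gaussian pixel noise, and an optional slow global
illumination drift. Every run is reproducible bit for bit from the seed,
and the generator returns per-frame ground truth (positions, rendered
pixel sets, true background, per-pixel coverage), so every other module
can be validated without real images.

Three deliberate idealisations matter for interpreting tests built on
these scenes: organisms are plain filled ellipses (no texture, no
shadows), their centroids are rounded to whole pixels before rendering
(so each organism covers the same number of pixels in every frame), and
the true background is clipped so the organism intensity offset never
saturates. Real images satisfy none of these exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import draw as _skdraw

from .errors import ValidationError
from .imaging import ImageStack, write_image

__all__ = [
    "SceneSpec",
    "OrganismState",
    "GroundTruth",
    "generate_scene",
    "generate_covered_scene",
    "coverage_fraction",
    "write_scene",
    "generate_batch",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic microcosm scene.

    ``length_mm`` is a distribution spec, ``("uniform", lo, hi)`` or
    ``("lognormal", mu_log, sigma_log)``; samples are clipped to
    [0.1, 3.0] mm. ``organism_intensity`` is the signed offset of organism
    pixels relative to the substrate (positive = brighter).
    ``illumination_drift`` is the additive grey-level change per frame
    (scalar slope) or an explicit per-frame offset sequence. With
    ``confine_to_cells`` each organism is restricted to its own grid cell;
    ``cell_margin_px >= 1`` then guarantees organisms can never touch, while
    ``0`` lets them touch (but never overlap) across cell borders.
    """

    seed: int
    frame_shape: tuple[int, int] = (160, 160)
    n_frames: int = 5
    n_organisms: int = 20
    length_mm: tuple = ("uniform", 0.3, 0.5)
    organism_intensity: int = 120
    base_level: int = 60
    gradient_amplitude: float = 20.0
    speckle_sigma: float = 6.0
    n_debris: int = 10
    debris_intensity: int = 60
    debris_radius_px: tuple[int, int] = (1, 3)
    step_px: float = 6.0
    noise_sigma: float = 0.0
    illumination_drift: float | Sequence[float] = 0.0
    pixels_per_mm: float = 20.0
    confine_to_cells: bool = False
    cell_margin_px: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for name in ("n_frames", "n_organisms", "n_debris"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.length_mm[0] not in ("uniform", "lognormal"):
            raise ValidationError(f"unknown length distribution {self.length_mm[0]!r}")


@dataclass(frozen=True)
class OrganismState:
    """Ground truth for one organism in one frame."""

    organism_id: int
    centroid: tuple[float, float]  # rendered (integer-pixel) centre, row/col
    length_mm: float
    orientation: float  # radians, 0 = major axis along columns
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) of rendered pixels


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about a scene."""

    true_background: np.ndarray
    frames: tuple[tuple[OrganismState, ...], ...]  # per frame, per organism
    coverage_map: np.ndarray  # per pixel: #frames in which it is organism-free
    spec: SceneSpec

    def occupancy_fraction(self) -> float:
        """Mean fraction of the frame covered by organisms, over frames."""
        n_px = self.true_background.size
        per_frame = [
            len(np.unique(np.ravel_multi_index(
                (np.concatenate([o.pixels[0] for o in states]),
                 np.concatenate([o.pixels[1] for o in states])),
                self.true_background.shape))) if states else 0
            for states in self.frames
        ]
        return float(np.mean(per_frame)) / n_px if per_frame else 0.0


def coverage_fraction(truth: GroundTruth) -> float:
    """Fraction of pixels that are organism-free in at least one frame.

    Exact background reconstruction by projection requires this to be 1.
    """
    return float(np.mean(truth.coverage_map >= 1))


def _sample_lengths(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.length_mm[0]
    if kind == "uniform":
        lo, hi = spec.length_mm[1], spec.length_mm[2]
        lengths = rng.uniform(lo, hi, spec.n_organisms)
    else:
        mu, sigma = spec.length_mm[1], spec.length_mm[2]
        lengths = rng.lognormal(mu, sigma, spec.n_organisms)
    return np.clip(lengths, 0.1, 3.0)


def _reflect(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return lo
    span = hi - lo
    # fold into [lo, lo + 2*span) then mirror
    y = (x - lo) % (2 * span)
    return lo + (y if y <= span else 2 * span - y)


def _cell_grid(n: int, shape: tuple[int, int]) -> tuple[int, int]:
    rows, cols = shape
    n_rows = max(1, int(round(math.sqrt(n * rows / cols))))
    n_cols = math.ceil(n / n_rows)
    while n_rows * n_cols < n:
        n_rows += 1
    return n_rows, n_cols


def generate_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a scene and its ground truth.

    Three independent, seed-derived random streams are consumed in a fixed
    documented order — background (gradient direction, speckle, debris),
    organisms (lengths, orientations, initial positions, walk angles), pixel
    noise — so changing the organism population never perturbs the
    background realisation.
    """
    rows, cols = spec.frame_shape
    rng_bg = np.random.default_rng([spec.seed % (2**31), 0])
    rng_org = np.random.default_rng([spec.seed % (2**31), 1])
    rng_noise = np.random.default_rng([spec.seed % (2**31), 2])

    # --- still background -------------------------------------------------
    phi = rng_bg.uniform(0, 2 * math.pi)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    axis = math.cos(phi) * (rr / max(rows - 1, 1) - 0.5) + math.sin(phi) * (
        cc / max(cols - 1, 1) - 0.5
    )
    bg = spec.base_level + spec.gradient_amplitude * axis
    if spec.speckle_sigma > 0:
        bg = bg + rng_bg.normal(0.0, spec.speckle_sigma, (rows, cols))
    for _ in range(spec.n_debris):
        r0 = rng_bg.uniform(0, rows)
        c0 = rng_bg.uniform(0, cols)
        rad = rng_bg.integers(spec.debris_radius_px[0], spec.debris_radius_px[1] + 1)
        dr, dc = _skdraw.disk((r0, c0), rad, shape=(rows, cols))
        bg[dr, dc] += spec.debris_intensity
    # keep the organism offset clip-free: bright organisms need headroom at
    # the top of the range, dark organisms at the bottom
    off = int(spec.organism_intensity)
    lo_clip, hi_clip = (0, 255 - off) if off >= 0 else (-off, 255)
    true_background = np.clip(np.floor(bg + 0.5), lo_clip, hi_clip).astype(np.uint8)

    # --- organisms ---------------------------------------------------------
    n = spec.n_organisms
    lengths = _sample_lengths(spec, rng_org)
    thetas = rng_org.uniform(0, 2 * math.pi, n)
    semi_major = lengths * spec.pixels_per_mm / 2.0
    semi_minor = np.maximum(semi_major / 3.0, 0.5)
    if n and 2 * semi_major.max() >= min(rows, cols):
        raise ValidationError(
            f"organism of length {2 * semi_major.max():.0f} px does not fit the "
            f"{rows}x{cols} frame"
        )

    bounds: list[tuple[float, float, float, float]] = []  # per organism r-lo, r-hi, c-lo, c-hi
    if spec.confine_to_cells and n:
        n_rows, n_cols = _cell_grid(n, (rows, cols))
        for k in range(n):
            i, j = divmod(k, n_cols)
            r_lo, r_hi = i * rows / n_rows, (i + 1) * rows / n_rows - 1
            c_lo, c_hi = j * cols / n_cols, (j + 1) * cols / n_cols - 1
            m = semi_major[k] + spec.cell_margin_px
            if r_lo + m > r_hi - m or c_lo + m > c_hi - m:
                raise ValidationError(
                    "cell too small for the organism: reduce n_organisms, "
                    "organism size or cell margin"
                )
            bounds.append((r_lo + m, r_hi - m, c_lo + m, c_hi - m))
    else:
        for k in range(n):
            m = semi_major[k]
            if m > (rows - 1) / 2 or m > (cols - 1) / 2:
                raise ValidationError("organism larger than the frame")
            bounds.append((m, rows - 1 - m, m, cols - 1 - m))

    pos = np.empty((n, 2))
    for k in range(n):
        r_lo, r_hi, c_lo, c_hi = bounds[k]
        pos[k, 0] = rng_org.uniform(r_lo, r_hi)
        pos[k, 1] = rng_org.uniform(c_lo, c_hi)
    walk_angles = rng_org.uniform(0, 2 * math.pi, (max(spec.n_frames - 1, 0), n))

    if np.isscalar(spec.illumination_drift):
        drift = [float(spec.illumination_drift) * t for t in range(spec.n_frames)]
    else:
        drift = [float(d) for d in spec.illumination_drift]
        if len(drift) != spec.n_frames:
            raise ValidationError("illumination_drift sequence length != n_frames")

    frames = np.empty((spec.n_frames, rows, cols), dtype=np.uint8)
    truth_frames: list[tuple[OrganismState, ...]] = []
    occupancy_total = np.zeros((rows, cols), dtype=np.int32)
    for t in range(spec.n_frames):
        if t > 0:
            for k in range(n):
                ang = walk_angles[t - 1, k]
                r_lo, r_hi, c_lo, c_hi = bounds[k]
                pos[k, 0] = _reflect(pos[k, 0] + spec.step_px * math.sin(ang), r_lo, r_hi)
                pos[k, 1] = _reflect(pos[k, 1] + spec.step_px * math.cos(ang), c_lo, c_hi)
        union = np.zeros((rows, cols), dtype=bool)
        states = []
        for k in range(n):
            r0, c0 = int(round(pos[k, 0])), int(round(pos[k, 1]))
            pr, pc = _skdraw.ellipse(
                r0, c0, semi_minor[k], semi_major[k],
                shape=(rows, cols), rotation=thetas[k],
            )
            if len(pr) == 0:
                pr = np.array([r0])
                pc = np.array([c0])
            union[pr, pc] = True
            states.append(
                OrganismState(
                    organism_id=k,
                    centroid=(float(r0), float(c0)),
                    length_mm=float(lengths[k]),
                    orientation=float(thetas[k]),
                    pixels=(pr, pc),
                )
            )
        img = true_background.astype(np.int32) + int(round(drift[t]))
        img[union] += off
        if spec.noise_sigma > 0:
            img = img + np.floor(
                rng_noise.normal(0.0, spec.noise_sigma, (rows, cols)) + 0.5
            ).astype(np.int32)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
        occupancy_total += union
        truth_frames.append(tuple(states))

    coverage = spec.n_frames - occupancy_total
    stack = ImageStack.from_arrays(frames)
    truth = GroundTruth(true_background, tuple(truth_frames), coverage, spec)
    return stack, truth


def generate_covered_scene(
    spec: SceneSpec, max_attempts: int = 50
) -> tuple[ImageStack, GroundTruth]:
    """First seeded realisation of ``spec`` with complete coverage.

    Regenerates the scene with deterministically derived sub-seeds until
    every pixel is organism-free in at least one frame (the precondition for
    exact background reconstruction). Raises if no realisation within
    ``max_attempts`` achieves it — a sign the density/frame-count combination
    cannot support exact reconstruction.
    """
    for attempt in range(max_attempts):
        trial = replace(spec, seed=(spec.seed + 7919 * attempt) % (2**31))
        stack, truth = generate_scene(trial)
        if coverage_fraction(truth) == 1.0:
            return stack, truth
    raise ValidationError(
        f"no fully covered realisation in {max_attempts} attempts; "
        "use more frames or fewer/smaller organisms"
    )


def write_scene(
    stack: ImageStack, out_dir: str | Path, prefix: str = "frame", fmt: str = "png"
) -> list[Path]:
    """Export frames as numbered image files (lexicographic = temporal order)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack.frames):
        p = out_dir / f"{prefix}_{i:04d}.{fmt}"
        write_image(frame, p)
        paths.append(p)
    return paths


def generate_batch(
    root_dir: str | Path,
    n_boxes: int,
    spec: SceneSpec,
    fmt: str = "png",
) -> dict[str, GroundTruth]:
    """Write a directory tree of synthetic boxes (one leaf dir per box).

    Box ``k`` uses the spec with seed ``spec.seed + k``. Returns ground truth
    keyed by box id (the directory name).
    """
    root = Path(root_dir)
    truths: dict[str, GroundTruth] = {}
    for k in range(n_boxes):
        box_spec = replace(spec, seed=(spec.seed + k) % (2**31))
        stack, truth = generate_scene(box_spec)
        box_id = f"box_{k:03d}"
        write_scene(stack, root / box_id, fmt=fmt)
        truths[box_id] = truth
    return truths
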