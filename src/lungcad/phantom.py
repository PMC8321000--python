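"""Seeded synthetic chest-CT phantom stacks with ground truth.

Every slice reproduces the four-region layout of a PNG-exported chest CT:
a black background, a dark-gray circular body rim, a bright chest-wall disc
carrying a few darker patches, and two dark lung fields (mirrored ellipses
with a sinusoidally perturbed boundary).  Into the lungs the generator plants

* **nodules** — bright spheres whose circular cross-sections share one center
  across adjacent slices, and
* **vessels** — bright oblique cylinders whose circular cross-sections drift
  by ``vessel_obliqueness`` pixels per slice (more than the default
  consistency match radius, so vessels fail the across-slice test by
  construction).

Intensities are perturbed by additive Gaussian noise and clipped to [0, 255].
Generation is fully deterministic given the seed, and the returned ground
truth (per-slice lung masks, nodule and vessel cross-sections) makes every
pipeline stage testable without any external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigError
from .io import GrayscaleSlice, SliceStack, write_mask_image
from .metrics import TruthEntry, write_truth

__all__ = [
    "PhantomConfig",
    "StructureTruth",
    "PhantomGroundTruth",
    "generate_stack",
    "export_phantom",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and planting parameters of the phantom.

    Intensity levels follow the four-peak histogram of a PNG chest-CT export
    (peaks at 0, ~60, ~210, 255): background 0, body rim and lung parenchyma
    at the same dark gray 60, chest wall 255 with patches at 210.  Nodules
    (210) are slightly brighter than vessels (190), both well above the
    parenchyma.  ``vessel_obliqueness`` (px drift per slice) exceeds the
    default consistency match radius so planted vessels are inconsistent
    across slices by construction.
    """

    rows: int = 256
    cols: int = 256
    n_slices: int = 9
    background_level: int = 0
    rim_level: int = 60
    wall_level: int = 255
    patch_level: int = 210
    lung_level: int = 60
    nodule_level: int = 210
    vessel_level: int = 190
    noise_sd: float = 5.0
    n_nodules: int = 2
    nodule_radius_range: Tuple[float, float] = (4.0, 7.0)
    nodule_half_extent: int = 2  # axial half extent in slices (span 2h+1)
    n_vessels: int = 3
    vessel_radius_range: Tuple[float, float] = (2.5, 4.5)
    vessel_obliqueness: float = 8.0
    n_patches: int = 5
    patch_radius_range: Tuple[float, float] = (5.0, 12.0)
    min_separation: float = 22.0
    lung_boundary_amp: float = 0.06
    lung_boundary_freq: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 64 or self.cols < 64:
            raise ConfigError("phantom slices must be at least 64x64")
        if self.n_slices < 1:
            raise ConfigError("need at least one slice")
        dark = max(self.background_level, self.rim_level, self.lung_level)
        bright = min(self.wall_level, self.patch_level, self.nodule_level, self.vessel_level)
        if not dark < bright:
            raise ConfigError(
                "region levels must keep background/rim/lung strictly below "
                "wall/patch/structure levels (four-peak histogram shape)"
            )
        for lo, hi in (self.nodule_radius_range, self.vessel_radius_range):
            if not 0 < lo <= hi:
                raise ConfigError("radius ranges must be positive and ordered")


@dataclass(frozen=True)
class StructureTruth:
    """Per-slice cross-sections of one planted structure."""

    kind: str  # "nodule" or "vessel"
    entries: Tuple[TruthEntry, ...]  # one per slice where the structure shows

    @property
    def slice_range(self) -> Tuple[int, int]:
        idx = [e.slice_index for e in self.entries]
        return (min(idx), max(idx))


@dataclass
class PhantomGroundTruth:
    """Everything the generator knows: lung masks and planted structures."""

    exam_id: str
    lung_masks: List[np.ndarray]  # per slice, bool
    nodules: List[StructureTruth] = field(default_factory=list)
    vessels: List[StructureTruth] = field(default_factory=list)

    def nodule_entries(self) -> List[TruthEntry]:
        return [e for s in self.nodules for e in s.entries]

    def vessel_entries(self) -> List[TruthEntry]:
        return [e for s in self.vessels for e in s.entries]

    def all_entries(self) -> List[TruthEntry]:
        return self.nodule_entries() + self.vessel_entries()


def _disc(rr: np.ndarray, cc: np.ndarray, center: Tuple[float, float], radius: float) -> np.ndarray:
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _lung_fields(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Two mirrored ellipses with sinusoidal boundary perturbation."""
    rr, cc = np.indices((cfg.rows, cfg.cols), dtype=np.float64)
    r0 = cfg.rows / 2.0
    a = 0.215 * cfg.rows  # row semi-axis
    b = 0.125 * cfg.cols  # col semi-axis
    mask = np.zeros((cfg.rows, cfg.cols), dtype=bool)
    for side in (-1.0, 1.0):
        c0 = cfg.cols / 2.0 + side * 0.175 * cfg.cols
        x = (rr - r0) / a
        y = (cc - c0) / b
        rho = np.sqrt(x**2 + y**2)
        theta = np.arctan2(y, x)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        wobble = 1.0 + cfg.lung_boundary_amp * np.sin(cfg.lung_boundary_freq * theta + phase)
        mask |= rho <= wobble
    return mask


def _sample_point(
    rng: np.random.Generator, allowed: np.ndarray
) -> Optional[Tuple[int, int]]:
    pts = np.argwhere(allowed)
    if len(pts) == 0:
        return None
    r, c = pts[int(rng.integers(len(pts)))]
    return int(r), int(c)


def _min_dist_ok(
    center: Tuple[float, float],
    slice_idx: int,
    placed: Sequence[Tuple[int, Tuple[float, float]]],
    min_sep: float,
) -> bool:
    for j, (r, c) in placed:
        if j == slice_idx and math.hypot(center[0] - r, center[1] - c) < min_sep:
            return False
    return True


def generate_stack(config: PhantomConfig) -> Tuple[SliceStack, PhantomGroundTruth]:
    """Render a seeded phantom stack and its ground truth.

    Deterministic given ``config`` (including its seed).  Raises
    :class:`ConfigError` when the requested structures cannot be placed
    inside the lungs with the configured margins.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    exam_id = f"phantom-{cfg.seed}"
    rr, cc = np.indices((cfg.rows, cfg.cols), dtype=np.float64)
    center = (cfg.rows / 2.0, cfg.cols / 2.0)
    body_r = 0.46 * min(cfg.rows, cfg.cols)
    wall_r = 0.40 * min(cfg.rows, cfg.cols)

    body = _disc(rr, cc, center, body_r)
    wall = _disc(rr, cc, center, wall_r)
    lungs = _lung_fields(cfg, rng)
    lungs &= wall  # lungs live strictly inside the chest wall

    canvas = np.full((cfg.rows, cfg.cols), float(cfg.background_level))
    canvas[body] = cfg.rim_level
    canvas[wall] = cfg.wall_level

    # darker patches inside the wall, clear of the lungs
    lung_dist = ndimage.distance_transform_edt(~lungs)
    for _ in range(cfg.n_patches):
        pr = rng.uniform(*cfg.patch_radius_range)
        for _attempt in range(200):
            pt = _sample_point(rng, wall & (lung_dist > pr + 4.0))
            if pt is None:
                break
            d_center = math.hypot(pt[0] - center[0], pt[1] - center[1])
            if d_center <= wall_r - pr - 2.0 and lung_dist[pt] > pr + 4.0:
                canvas[_disc(rr, cc, pt, pr)] = cfg.patch_level
                break

    canvas[lungs] = cfg.lung_level

    # structure placement uses the distance to the lung boundary
    inner_dist = ndimage.distance_transform_edt(lungs)
    placed: List[Tuple[int, Tuple[float, float]]] = []  # (slice_index, center)

    # vessels first: their drifting paths are the most constrained geometry
    vessels: List[StructureTruth] = []
    vessel_discs: List[Tuple[int, Tuple[float, float], float]] = []
    if cfg.n_vessels and not (inner_dist >= cfg.vessel_radius_range[0] + 3.0).any():
        raise ConfigError("vessel radius does not fit inside the lungs")
    for _ in range(cfg.n_vessels):
        for attempt in range(5000):
            radius = rng.uniform(*cfg.vessel_radius_range)
            phi = rng.uniform(-0.35, 0.35)
            sign = -1.0 if rng.random() < 0.5 else 1.0
            direction = (sign * math.cos(phi), math.sin(phi))  # mostly along rows
            start = _sample_point(rng, inner_dist >= radius + 3.0)
            if start is None:
                continue
            path = []
            for j in range(1, cfg.n_slices + 1):
                drift = cfg.vessel_obliqueness * (j - 1)
                path.append((start[0] + direction[0] * drift, start[1] + direction[1] * drift))
            if not all(
                0 <= int(round(p[0])) < cfg.rows
                and 0 <= int(round(p[1])) < cfg.cols
                and inner_dist[int(round(p[0])), int(round(p[1]))] >= radius + 3.0
                for p in path
            ):
                continue
            if not all(
                _min_dist_ok(p, j, placed, cfg.min_separation)
                for j, p in zip(range(1, cfg.n_slices + 1), path)
            ):
                continue
            entries = []
            for j, p in zip(range(1, cfg.n_slices + 1), path):
                vessel_discs.append((j, p, radius))
                entries.append(
                    TruthEntry(
                        exam_id=exam_id,
                        slice_index=j,
                        center=p,
                        radius_px=radius,
                        kind="vessel",
                    )
                )
                placed.append((j, p))
            vessels.append(StructureTruth(kind="vessel", entries=tuple(entries)))
            break
        else:
            raise ConfigError("could not place a vessel inside the lungs")

    nodules: List[StructureTruth] = []
    nodule_discs: List[Tuple[int, Tuple[float, float], float]] = []  # (slice, center, r)
    h = cfg.nodule_half_extent
    if cfg.n_slices < 2 * h + 1 and cfg.n_nodules > 0:
        raise ConfigError("stack too shallow for the configured nodule extent")
    if cfg.n_nodules and not (inner_dist >= cfg.nodule_radius_range[0] + 4.0).any():
        raise ConfigError("nodule radius does not fit inside the lungs")
    for _ in range(cfg.n_nodules):
        for attempt in range(5000):
            radius = rng.uniform(*cfg.nodule_radius_range)
            j0 = int(rng.integers(h + 1, cfg.n_slices - h + 1))  # 1-based center slice
            pt = _sample_point(rng, inner_dist >= radius + 4.0)
            if pt is None:
                continue
            ok = all(
                _min_dist_ok(pt, j, placed, cfg.min_separation)
                for j in range(1, cfg.n_slices + 1)
            )
            if not ok:
                continue
            entries = []
            for j in range(j0 - h, j0 + h + 1):
                d = j - j0
                r_j = radius * math.sqrt(max(0.0, 1.0 - (d / (h + 0.5)) ** 2))
                nodule_discs.append((j, (float(pt[0]), float(pt[1])), r_j))
                if r_j >= 2.0:
                    entries.append(
                        TruthEntry(
                            exam_id=exam_id,
                            slice_index=j,
                            center=(float(pt[0]), float(pt[1])),
                            radius_px=r_j,
                            kind="nodule",
                        )
                    )
                placed.append((j, (float(pt[0]), float(pt[1]))))
            nodules.append(StructureTruth(kind="nodule", entries=tuple(entries)))
            break
        else:
            raise ConfigError("could not place a nodule inside the lungs")

    slices = []
    for j in range(1, cfg.n_slices + 1):
        img = canvas.copy()
        for jj, c0, r_j in nodule_discs:
            if jj == j and r_j >= 0.5:
                img[_disc(rr, cc, c0, r_j)] = cfg.nodule_level
        for jj, c0, r_j in vessel_discs:
            if jj == j:
                img[_disc(rr, cc, c0, r_j)] = cfg.vessel_level
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        slices.append(
            GrayscaleSlice(pixels=img, slice_index=j, source_id=f"{exam_id}-s{j:03d}")
        )

    stack = SliceStack(slices=slices, spacing_mm=None, exam_id=exam_id)
    truth = PhantomGroundTruth(
        exam_id=exam_id,
        lung_masks=[lungs.copy() for _ in range(cfg.n_slices)],
        nodules=nodules,
        vessels=vessels,
    )
    return stack, truth


def export_phantom(
    stack: SliceStack,
    truth: PhantomGroundTruth,
    directory,
    *,
    write_lung_masks: bool = False,
) -> None:
    """Write the phantom as PNG slices plus a JSON-lines ground-truth file.

    Slice files are named ``slice_###.png`` so lexicographic order equals
    slice order; the truth file ``truth.jsonl`` uses the evaluation module's
    format and includes both nodule and vessel entries (the ``kind`` field
    distinguishes them).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(stack) == 0:
        raise ConfigError("cannot export an empty stack")
    for s in stack:
        Image.fromarray(s.pixels, mode="L").save(
            directory / f"slice_{s.slice_index:03d}.png", format="PNG"
        )
    write_truth(truth.all_entries(), directory / "truth.jsonl")
    if write_lung_masks:
        mask_dir = directory / "lung_masks"
        mask_dir.mkdir(exist_ok=True)
        for j, mask in enumerate(truth.lung_masks, start=1):
            write_mask_image(mask, mask_dir / f"mask_{j:03d}.png")
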