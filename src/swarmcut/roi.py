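"""Computing-space reduction: bounding-box crop and crossline quadrant elimination.

Before the 3D graph is built, the volume is cropped to a bounding box around
the liver and, optionally, the quadrant of the axial plane posterior-right of
a "crossline" centred on the spine is excluded outright (those voxels are
anatomically never liver and receive hard background links downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CTVolume, SeedSet

__all__ = [
    "Crossline",
    "CropResult",
    "crop_bbox",
    "auto_bbox",
    "detect_crossline",
    "eliminate_quadrant",
    "embed_mask",
]

DEFAULT_BONE_THRESHOLD_HU = 200.0
QUADRANT_SIDES = ("right-bottom", "right-top", "left-bottom", "left-top")


@dataclass(frozen=True)
class Crossline:
    """Axial-plane (row, column) position of the spine centre, shared by all slices."""

    center: tuple[int, int]


@dataclass(frozen=True)
class CropResult:
    volume: CTVolume
    offset: tuple[int, int, int]  # index of the subvolume's (0,0,0) in the original grid
    original_shape: tuple[int, int, int]


def crop_bbox(volume: CTVolume, bbox: tuple[tuple[int, int], ...]) -> CropResult:
    """Crop to inclusive per-axis index ranges, recording the offset for re-embedding."""
    if len(bbox) != 3:
        raise ValueError("bbox must give (lo, hi) for each of the 3 axes")
    slices = []
    offset = []
    for ax, (lo, hi) in enumerate(bbox):
        lo, hi = int(lo), int(hi)
        if not (0 <= lo <= hi < volume.shape[ax]):
            raise ValueError(f"empty or out-of-range bbox on axis {ax}: ({lo}, {hi})")
        slices.append(slice(lo, hi + 1))
        offset.append(lo)
    sub = volume.intensities[tuple(slices)]
    origin = tuple(o + off * sp for o, off, sp in zip(volume.origin, offset, volume.spacing))
    return CropResult(CTVolume(sub.copy(), volume.spacing, origin), tuple(offset), volume.shape)


def auto_bbox(volume: CTVolume, seeds: SeedSet, margin_mm: float = 30.0) -> tuple[tuple[int, int], ...]:
    """Tight box around all seed voxels, dilated by ``margin_mm`` per axis."""
    anyseed = seeds.object_mask | seeds.background_mask
    if not anyseed.any():
        raise ValueError("cannot derive a bbox from an empty seed set")
    idx = np.nonzero(anyseed)
    bbox = []
    for ax in range(3):
        pad = int(np.ceil(margin_mm / volume.spacing[ax]))
        lo = max(0, int(idx[ax].min()) - pad)
        hi = min(volume.shape[ax] - 1, int(idx[ax].max()) + pad)
        bbox.append((lo, hi))
    return tuple(bbox)


def detect_crossline(volume: CTVolume, bone_threshold: float = DEFAULT_BONE_THRESHOLD_HU) -> Crossline:
    """Locate the spine centre as the centroid of bone-bright voxels.

    Only the posterior half (larger row indices) of the middle slice is
    considered, so bright anterior structures (contrast pooling, ribs cut
    obliquely) do not drag the centroid forward.
    """
    mid = volume.intensities[volume.shape[0] // 2]
    nr = mid.shape[0]
    posterior = mid[nr // 2 :]
    rows, cols = np.nonzero(posterior > bone_threshold)
    if rows.size == 0:
        raise ValueError(
            f"no voxels above {bone_threshold} HU in the posterior half of the mid slice; "
            "supply the crossline manually"
        )
    center = (int(round(rows.mean())) + nr // 2, int(round(cols.mean())))
    return Crossline(center)


def eliminate_quadrant(
    volume: CTVolume, crossline: Crossline, side: str = "right-bottom"
) -> np.ndarray:
    """Boolean exclusion mask for the chosen axial quadrant of the crossline.

    ``right-bottom`` (default) excludes voxels with row >= center.row and
    column >= center.column on every slice; the side is configurable because
    patient orientation conventions vary between scanners.
    """
    if side not in QUADRANT_SIDES:
        raise ValueError(f"side must be one of {QUADRANT_SIDES}")
    nz, nr, nc = volume.shape
    r0, c0 = crossline.center
    if not (0 <= r0 < nr and 0 <= c0 < nc):
        raise ValueError(f"crossline center {crossline.center} outside the grid")
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    vert = rows >= r0 if "bottom" in side else rows <= r0
    horiz = cols >= c0 if "right" in side else cols <= c0
    plane = vert & horiz
    return np.broadcast_to(plane, (nz, nr, nc)).copy()


def check_exclusion(seeds: SeedSet, exclusion: np.ndarray) -> None:
    """Seeds are ground truth: excluding an object-seed voxel is an error."""
    if np.any(seeds.object_mask & exclusion):
        raise ValueError("ROI reduction would remove object-seed voxels; adjust bbox/crossline")


def embed_mask(labels: np.ndarray, crop: CropResult) -> np.ndarray:
    """Re-embed a cropped label grid into the original volume's coordinates."""
    full = np.zeros(crop.original_shape, dtype=bool)
    z0, r0, c0 = crop.offset
    nz, nr, nc = labels.shape
    full[z0 : z0 + nz, r0 : r0 + nr, c0 : c0 + nc] = labels
    return full
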