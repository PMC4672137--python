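"""Five-metric segmentation evaluation and challenge-style scoring.

Errors between a predicted and a reference mask:

* VOE  — volumetric overlap error, 100 * (1 - |A n B| / |A u B|), percent;
* RVD  — relative volume difference, 100 * (|A| - |B|) / |B|, signed percent
  (scored by absolute value);
* ASD / RMSD / MSD — average / root-mean-square / maximum symmetric surface
  distance in mm between the 6-connectivity border voxels of the two masks.

Each error maps to a score on [0, 100] by the linear ramp through two anchor
points: zero error scores 100, and the reference inter-rater errors
(6.4 %, 4.7 %, 1.0 mm, 1.8 mm, 19.0 mm) score 75:

    score = max(0, 100 - 25 * error / reference_error)

The total score is the mean of the five per-metric scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import SegmentationMask

__all__ = [
    "ErrorMetrics",
    "ReferenceErrors",
    "ScoreReport",
    "DEFAULT_REFERENCE",
    "volume_overlap_error",
    "relative_volume_difference",
    "surface_distances",
    "evaluate_masks",
    "metric_score",
    "total_score",
]

METRIC_NAMES = ("voe", "rvd", "asd", "rmsd", "msd")


@dataclass(frozen=True)
class ErrorMetrics:
    """The five error measures: voe/rvd in %, asd/rmsd/msd in mm."""

    voe: float
    rvd: float
    asd: float
    rmsd: float
    msd: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.voe, self.rvd, self.asd, self.rmsd, self.msd)


@dataclass(frozen=True)
class ReferenceErrors:
    """Per-metric reference errors that anchor the 75-point score level."""

    voe: float = 6.4
    rvd: float = 4.7
    asd: float = 1.0
    rmsd: float = 1.8
    msd: float = 19.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (self.voe, self.rvd, self.asd, self.rmsd, self.msd)):
            raise ValueError("reference errors must be positive")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.voe, self.rvd, self.asd, self.rmsd, self.msd)


DEFAULT_REFERENCE = ReferenceErrors()


@dataclass(frozen=True)
class ScoreReport:
    scores: tuple[float, float, float, float, float]
    total: float


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.labels
    return np.asarray(mask, dtype=bool)


def volume_overlap_error(a, b) -> float:
    """VOE in percent: 100 * (1 - |A n B| / |A u B|)."""
    a, b = _as_bool(a), _as_bool(b)
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("both masks are empty")
    inter = np.count_nonzero(a & b)
    return 100.0 * (1.0 - inter / union)


def relative_volume_difference(a, b) -> float:
    """Signed RVD in percent: 100 * (|A| - |B|) / |B| against reference mask B."""
    a, b = _as_bool(a), _as_bool(b)
    nb = np.count_nonzero(b)
    if nb == 0:
        raise ValueError("reference mask is empty")
    return 100.0 * (np.count_nonzero(a) - nb) / nb


_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _border(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)


def surface_distances(a, b, spacing=(1.0, 1.0, 1.0)) -> tuple[float, float, float]:
    """(ASD, RMSD, MSD) in mm between the border voxels of two masks.

    Border voxels are mask voxels with at least one background 6-neighbour
    (volume-boundary voxels count as border). Distances are voxel-centre
    distances from each surface voxel to the nearest voxel of the other
    surface, pooled symmetrically over both surfaces.
    """
    if isinstance(a, SegmentationMask):
        spacing = a.spacing
    a, b = _as_bool(a), _as_bool(b)
    if not a.any() or not b.any():
        raise ValueError("surface distances need two non-empty masks")
    border_a, border_b = _border(a), _border(b)
    dt_to_b = ndimage.distance_transform_edt(~border_b, sampling=spacing)
    dt_to_a = ndimage.distance_transform_edt(~border_a, sampling=spacing)
    d = np.concatenate([dt_to_b[border_a], dt_to_a[border_b]])
    return (float(d.mean()), float(np.sqrt(np.mean(d * d))), float(d.max()))


def evaluate_masks(pred, ref, spacing=(1.0, 1.0, 1.0)) -> ErrorMetrics:
    """All five errors of a predicted mask against a reference mask."""
    if isinstance(pred, SegmentationMask):
        spacing = pred.spacing
    asd, rmsd, msd = surface_distances(pred, ref, spacing)
    return ErrorMetrics(
        voe=volume_overlap_error(pred, ref),
        rvd=relative_volume_difference(pred, ref),
        asd=asd,
        rmsd=rmsd,
        msd=msd,
    )


def metric_score(error: float, reference: float) -> float:
    """Linear score through (0, 100) and (reference, 75), clamped at 0."""
    if reference <= 0:
        raise ValueError("reference error must be positive")
    if error < 0:
        raise ValueError("error must be non-negative (take |RVD| before scoring)")
    return max(0.0, 100.0 - 25.0 * error / reference)


def total_score(errors: ErrorMetrics, refs: ReferenceErrors = DEFAULT_REFERENCE) -> ScoreReport:
    """Per-metric scores (RVD by absolute value) and their mean."""
    evals = (abs(errors.voe), abs(errors.rvd), errors.asd, errors.rmsd, errors.msd)
    scores = tuple(metric_score(e, r) for e, r in zip(evals, refs.as_tuple()))
    return ScoreReport(scores=scores, total=float(np.mean(scores)))
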