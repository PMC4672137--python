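"""Model/Results interface over the full segmentation pipeline.

:class:`LiverSegmentation` is constructed from the data (a CT volume plus a
seed set) and a :class:`~swarmcut.config.PipelineConfig`; :meth:`fit` runs

    ROI reduction -> appearance-certainty enhancement -> variant ACO ->
    likelihood propagation -> modulated graph cut

and returns a :class:`SegmentationResult` holding the mask in the original
grid, the max-flow value, the labelling energy, the intermediate fields and a
provenance record (config hash, seed, problem sizes) sufficient to reproduce
the mask exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from typing import Any

import numpy as np

from . import __version__
from .aco import ACOParams, run_variant_aco
from .config import PipelineConfig
from .enhancement import enhanced_image
from .graphcut import segment_volume
from .likelihood import LikelihoodField, compute_likelihood_field
from .metrics import ErrorMetrics, ScoreReport, evaluate_masks, total_score
from .roi import (
    CropResult,
    Crossline,
    auto_bbox,
    check_exclusion,
    crop_bbox,
    detect_crossline,
    eliminate_quadrant,
    embed_mask,
)
from .volume import CTVolume, SeedSet, SegmentationMask

__all__ = ["LiverSegmentation", "SegmentationResult"]


@dataclass
class SegmentationResult:
    """Fitted segmentation: mask, energy diagnostics and stage artifacts."""

    mask: SegmentationMask
    flow: float
    energy: float
    likelihoods: LikelihoodField
    tau: np.ndarray | None
    enhanced: np.ndarray | None
    crop: CropResult
    provenance: dict[str, Any]

    def score(self, reference: SegmentationMask | np.ndarray) -> tuple[ErrorMetrics, ScoreReport]:
        """Five-metric errors and challenge score against a reference mask."""
        errors = evaluate_masks(self.mask, reference, self.mask.spacing)
        return errors, total_score(errors)

    def summary(self, reference: SegmentationMask | np.ndarray | None = None) -> str:
        """Human-readable fit report, statsmodels-style."""
        lines = [
            "Swarm-modulated graph-cut segmentation",
            "=" * 46,
            f"grid (ROI)        : {self.provenance['roi_shape']}  of  {self.provenance['volume_shape']}",
            f"spacing [mm]      : {self.provenance['spacing']}",
            f"object voxels     : {int(self.mask.labels.sum())}",
            f"max-flow value    : {self.flow:.4f}",
            f"labelling energy  : {self.energy:.4f}",
            f"swarm stage       : {'on' if self.tau is not None else 'off (plain graph cut)'}",
            f"config digest     : {self.provenance['config_digest']}  seed: {self.provenance['seed']}",
        ]
        if reference is not None:
            errors, report = self.score(reference)
            lines += [
                "-" * 46,
                f"VOE  [%]  : {errors.voe:8.2f}   score {report.scores[0]:6.2f}",
                f"RVD  [%]  : {errors.rvd:8.2f}   score {report.scores[1]:6.2f}",
                f"ASD  [mm] : {errors.asd:8.2f}   score {report.scores[2]:6.2f}",
                f"RMSD [mm] : {errors.rmsd:8.2f}   score {report.scores[3]:6.2f}",
                f"MSD  [mm] : {errors.msd:8.2f}   score {report.scores[4]:6.2f}",
                f"total score       : {report.total:.2f}",
            ]
        return "\n".join(lines)


class LiverSegmentation:
    """Seeded 3D segmentation model over a CT volume.

    Parameters
    ----------
    volume
        The CT volume (HU) to segment.
    seeds
        Disjoint object/background seed masks congruent with the volume.
    config
        Full pipeline configuration; defaults reproduce the standard
        parameterization (lambda = 0.15, mu1 = 12, mu2 = 8, sigma = 10 HU).
    """

    def __init__(self, volume: CTVolume, seeds: SeedSet, config: PipelineConfig | None = None):
        if seeds.object_mask.shape != volume.shape:
            raise ValueError("seeds not congruent with volume")
        seeds.require_nonempty()
        self.volume = volume
        self.seeds = seeds
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(
        cls, volume_path, seed_path, config: PipelineConfig | None = None, volume_format: str | None = None
    ) -> "LiverSegmentation":
        """Build the model from a volume file/directory and a 0/1/2 seed label mask."""
        from .volume import read_volume, seeds_from_label_mask

        volume = read_volume(volume_path, volume_format)
        seeds = seeds_from_label_mask(seed_path)
        return cls(volume, seeds, config)

    # ------------------------------------------------------------------

    def _reduce(self) -> tuple[CropResult, SeedSet, np.ndarray | None]:
        cfg = self.config.roi
        if cfg.bbox_mode == "full":
            bbox = tuple((0, n - 1) for n in self.volume.shape)
        elif cfg.bbox_mode == "manual":
            bbox = cfg.bbox
        else:
            bbox = auto_bbox(self.volume, self.seeds, cfg.margin_mm)
        crop = crop_bbox(self.volume, bbox)
        sl = tuple(slice(lo, hi + 1) for lo, hi in bbox)
        if not self.seeds.object_mask[sl].any():
            raise ValueError("bounding box removes all object seeds")
        seeds = SeedSet(self.seeds.object_mask[sl], self.seeds.background_mask[sl])

        exclusion = None
        if cfg.crossline is not None:
            if cfg.crossline == "auto":
                cl = detect_crossline(crop.volume, cfg.bone_threshold)
            else:
                r, c = cfg.crossline
                cl = Crossline((int(r) - crop.offset[1], int(c) - crop.offset[2]))
            exclusion = eliminate_quadrant(crop.volume, cl, cfg.quadrant_side)
            check_exclusion(seeds, exclusion)
        return crop, seeds, exclusion

    def fit(self) -> SegmentationResult:
        """Run the full pipeline and return the fitted result."""
        t0 = time.perf_counter()
        cfg = self.config
        crop, seeds, exclusion = self._reduce()
        roi = crop.volume

        enhanced = None
        tau = None
        if cfg.use_aco:
            enhanced = enhanced_image(roi, seeds, cfg.enhancement)
            tau = np.empty(roi.shape, dtype=np.float64)
            for z in range(roi.shape[0]):
                params = replace(cfg.aco, seed=(cfg.aco.seed + cfg.seed * 100003 + z) % (2**31))
                tau[z] = run_variant_aco(enhanced[z], params)

        likelihoods = compute_likelihood_field(
            roi,
            seeds,
            cfg.connectivity,
            cfg.interval,
            use_intensity_weight=cfg.use_intensity_weight,
        )
        roi_mask, flow, energy = segment_volume(
            roi, likelihoods, seeds, cfg.energy, tau, exclusion
        )
        full_labels = embed_mask(roi_mask.labels, crop)
        mask = SegmentationMask(full_labels, self.volume.spacing, self.volume.origin)

        provenance = {
            "package": "swarmcut",
            "version": __version__,
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "volume_shape": tuple(self.volume.shape),
            "roi_shape": tuple(roi.shape),
            "roi_offset": tuple(crop.offset),
            "spacing": tuple(round(s, 6) for s in self.volume.spacing),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        return SegmentationResult(
            mask=mask,
            flow=flow,
            energy=energy,
            likelihoods=likelihoods,
            tau=tau,
            enhanced=enhanced,
            crop=crop,
            provenance=provenance,
        )
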