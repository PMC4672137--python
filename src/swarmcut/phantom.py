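"""Deterministic synthetic abdominal CT phantom with ground truth and seeds.

The phantom emulates the two failure regimes that motivate the pipeline:

* an adjacent organ sharing a face with the liver at a configurable HU
  offset ``organ_delta`` — ``organ_delta`` near 0 reproduces the
  "special slice" regime where the shared boundary is nearly iso-intense
  and invisible to a plain Gaussian boundary term;
* bright tubular vessels inside the liver — the intensity-diversity regime
  that creates false internal edges.

Geometry is an ellipsoidal liver with a lobe bulge, a smaller ellipsoidal
adjacent organ touching it, optional vessels, a posterior bone cylinder (for
spine/crossline detection tests), soft-tissue background and an air rim.
Boundaries are blurred by a Gaussian point-spread in mm and i.i.d. Gaussian
HU noise is added; everything is reproducible from ``rng_seed``.

Seeds are auto-placed the way an operator would: object seeds as an eroded
liver core (healthy tissue well inside the organ), background seeds inside
the adjacent organ (hugging the ambiguous boundary from outside) plus a far
background shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTVolume, SeedSet

__all__ = ["PhantomSpec", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast of the synthetic abdomen.

    HU palette defaults are representative of contrast-enhanced CT: liver 110,
    vessels 180, background soft tissue 40, air -1000, bone 700. The adjacent
    organ sits at ``liver_hu + organ_delta``.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    liver_hu: float = 110.0
    organ_delta: float = 60.0
    vessel_hu: float = 180.0
    background_hu: float = 40.0
    air_hu: float = -1000.0
    bone_hu: float = 700.0
    with_vessels: bool = True
    with_bone: bool = True
    blur_mm: float = 1.0
    noise_hu: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 24:
            raise ValueError("phantom grid must be at least 24 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.blur_mm < 0 or self.noise_hu < 0:
            raise ValueError("blur and noise levels must be non-negative")


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[CTVolume, np.ndarray, SeedSet]:
    """Build (volume, ground-truth liver mask, seeds) for a phantom spec."""
    nz, nr, nc = spec.shape
    rng = np.random.default_rng(spec.rng_seed)

    # liver: ellipsoid in the anterior-left of the body, plus a lobe bulge;
    # sized to fill a realistic fraction (~1/5) of a tightly cropped liver ROI
    liver_center = (nz * 0.50, nr * 0.42, nc * 0.40)
    liver_semi = (nz * 0.36, nr * 0.29, nc * 0.30)
    liver = _ellipsoid(spec.shape, liver_center, liver_semi)
    lobe = _ellipsoid(
        spec.shape,
        (nz * 0.42, nr * 0.56, nc * 0.58),
        (nz * 0.18, nr * 0.15, nc * 0.16),
    )
    liver |= lobe

    # adjacent organ: ellipsoid pressed into the liver's left flank; the
    # overlap is carved away so the two regions stay disjoint while sharing a
    # broad boundary face — the "special slice" situation when organ_delta ~ 0
    organ = _ellipsoid(
        spec.shape,
        (nz * 0.52, nr * 0.42, nc * 0.82),
        (nz * 0.28, nr * 0.24, nc * 0.26),
    )
    organ &= ~liver
    if not organ.any() or not liver.any():
        raise ValueError("degenerate phantom geometry: empty liver or adjacent organ")

    # body (soft tissue) ellipse per slice; outside is air
    body = _ellipsoid(spec.shape, (nz * 0.5, nr * 0.5, nc * 0.5), (nz * 2.0, nr * 0.48, nc * 0.48))

    img = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    img[body] = spec.background_hu
    img[liver] = spec.liver_hu
    img[organ] = spec.liver_hu + spec.organ_delta

    vessels = np.zeros(spec.shape, dtype=bool)
    if spec.with_vessels:
        zz, rr0, cc0 = np.ogrid[0:nz, 0:nr, 0:nc]
        for frac_r, frac_c in ((0.40, 0.38), (0.48, 0.30)):
            tube = (rr0 - nr * frac_r) ** 2 + (cc0 - nc * frac_c) ** 2 <= (nr * 0.03) ** 2
            vessels |= np.broadcast_to(tube, spec.shape)
        vessels &= ndimage.binary_erosion(liver, iterations=2)
        img[vessels] = spec.vessel_hu

    if spec.with_bone:
        zz, rr0, cc0 = np.ogrid[0:nz, 0:nr, 0:nc]
        bone = (rr0 - nr * 0.82) ** 2 + (cc0 - nc * 0.5) ** 2 <= (nr * 0.05) ** 2
        img[np.broadcast_to(bone, spec.shape) & body] = spec.bone_hu

    if spec.blur_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=[spec.blur_mm / s for s in spec.spacing])
    if spec.noise_hu > 0:
        img = img + rng.normal(0.0, spec.noise_hu, size=spec.shape)

    truth = liver | vessels  # vessels are liver tissue for the segmentation target

    # seeds: eroded liver core (object); adjacent organ interior + far
    # background shell (background)
    core = ndimage.binary_erosion(truth, structure=np.ones((3, 3, 3)), iterations=4)
    if not core.any():
        raise ValueError("degenerate phantom geometry: liver too small to seed")
    organ_core = ndimage.binary_erosion(organ, iterations=2)
    far = ~ndimage.binary_dilation(truth | organ, iterations=8)
    background = organ_core | far
    if not background.any():
        raise ValueError("degenerate phantom geometry: no background seed region")

    volume = CTVolume(img, spec.spacing)
    return volume, truth, SeedSet(core, background)
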