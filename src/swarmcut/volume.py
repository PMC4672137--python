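"""Core image-domain types and volume/mask/seed I/O.

Axis convention: all grids are indexed ``(slice, row, column)`` with 0-based
indices; ``spacing`` is the per-axis voxel size in millimetres in the same
order. Physical distances everywhere in the package are computed in mm from
this spacing, because the surface evaluation metrics are defined in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from skimage.draw import polygon as _fill_polygon

__all__ = [
    "CTVolume",
    "SeedSet",
    "SegmentationMask",
    "FormatError",
    "SeedOverlapError",
    "read_volume",
    "write_mask",
    "read_mask",
    "rasterize_seeds",
    "seeds_from_label_mask",
]

VOLUME_FORMATS = ("dicom-series", "nifti", "metaimage")

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mhd", ".mha")


class FormatError(ValueError):
    """An image file or directory could not be read/written in the stated format."""


class SeedOverlapError(ValueError):
    """Object and background seed regions intersect (they must be disjoint)."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with physical geometry.

    Parameters
    ----------
    intensities
        3D array, axis order (slice, row, column), HU.
    spacing
        Per-axis voxel size in mm, same axis order; strictly positive.
    origin
        Physical offset of voxel (0, 0, 0) in mm.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 3D grid")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class SeedSet:
    """Disjoint user-marked object (liver) and background voxel sets.

    The two masks are boolean grids congruent with a :class:`CTVolume`.
    Disjointness is a hard invariant checked on every construction path.
    """

    object_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        obj = np.asarray(self.object_mask, dtype=bool)
        bkg = np.asarray(self.background_mask, dtype=bool)
        if obj.shape != bkg.shape:
            raise ValueError("object and background masks must be congruent")
        if np.any(obj & bkg):
            raise SeedOverlapError("object and background seed regions overlap")
        object.__setattr__(self, "object_mask", obj)
        object.__setattr__(self, "background_mask", bkg)

    def require_nonempty(self) -> None:
        if not self.object_mask.any():
            raise ValueError("object seed set is empty")
        if not self.background_mask.any():
            raise ValueError("background seed set is empty")


@dataclass(frozen=True)
class SegmentationMask:
    """Binary labelling of a volume (True = object/liver), with spacing in mm."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=bool)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _from_sitk(img: sitk.Image) -> CTVolume:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x) == (slice, row, column)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return CTVolume(arr.astype(np.float32), spacing, origin)


def _to_sitk(arr: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed([float(s) for s in spacing])))
    img.SetOrigin(tuple(reversed([float(o) for o in origin])))
    return img


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM files in {path}")
    try:
        datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    except AttributeError:
        datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
        zpos = None

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    arr = np.stack(slices, axis=0)

    ref = datasets[0]
    try:
        row_sp, col_sp = (float(v) for v in ref.PixelSpacing)
    except AttributeError as exc:
        raise FormatError(f"DICOM series in {path} lacks PixelSpacing") from exc

    if zpos is not None and len(zpos) > 1:
        gaps = np.diff(zpos)
        slice_sp = float(np.median(gaps))
        if slice_sp <= 0:
            raise FormatError(f"non-increasing slice positions in {path}")
        if not np.allclose(gaps, slice_sp, rtol=0, atol=1e-3):
            warnings.warn(
                f"inconsistent slice spacing in {path} "
                f"(range {gaps.min():.4g}-{gaps.max():.4g} mm); using median {slice_sp:.4g} mm",
                stacklevel=3,
            )
    else:
        slice_sp = float(getattr(ref, "SliceThickness", 1.0))
    origin = (0.0, 0.0, 0.0)
    if zpos is not None:
        ipp = ref.ImagePositionPatient
        origin = (float(zpos[0]), float(ipp[1]), float(ipp[0]))
    return CTVolume(arr, (slice_sp, row_sp, col_sp), origin)


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom-series"
    name = path.name.lower()
    if name.endswith(_NIFTI_EXT):
        return "nifti"
    if name.endswith(_META_EXT):
        return "metaimage"
    raise FormatError(f"cannot infer image format from {path}")


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a DICOM series directory, NIfTI or MetaImage file.

    DICOM pixel data is rescaled to HU via slope/intercept. If the slice
    positions in a series are unevenly spaced, a warning is emitted and the
    median gap is used as slice spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)
    if fmt not in VOLUME_FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {VOLUME_FORMATS}")
    if fmt == "dicom-series":
        if not path.is_dir():
            raise FormatError(f"dicom-series format requires a directory: {path}")
        return _read_dicom_series(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    return _from_sitk(img)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha)."""
    path = Path(path)
    name = path.name.lower()
    if not (name.endswith(_NIFTI_EXT) or name.endswith(_META_EXT)):
        raise FormatError(f"unsupported volume extension: {path.name}")
    sitk.WriteImage(_to_sitk(volume.intensities.astype(np.float32), volume.spacing, volume.origin), str(path))


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a binary mask losslessly (uint8 0/1) as NIfTI or MetaImage."""
    path = Path(path)
    name = path.name.lower()
    if not (name.endswith(_NIFTI_EXT) or name.endswith(_META_EXT)):
        raise FormatError(f"unsupported mask extension: {path.name}")
    sitk.WriteImage(_to_sitk(mask.labels.astype(np.uint8), mask.spacing, mask.origin), str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    vol = _from_sitk(img)
    return SegmentationMask(vol.intensities > 0.5, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedContour:
    """One closed polygon (row, column vertices) extruded over a slice range."""

    label: str  # "object" | "background"
    slice_range: tuple[int, int]  # inclusive start/end slice
    vertices: np.ndarray = field(repr=False)  # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        if self.label not in ("object", "background"):
            raise ValueError(f"contour label must be object|background, got {self.label!r}")
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour needs >= 3 (row, col) vertices")
        object.__setattr__(self, "vertices", v)


def _check_simple_polygon(vertices: np.ndarray) -> None:
    from shapely.geometry import Polygon

    poly = Polygon(vertices)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("seed polygon must be closed, non-self-intersecting and have positive area")


def rasterize_seeds(contours: list[SeedContour], volume: CTVolume) -> SeedSet:
    """Fill each closed contour on every slice of its range (cylindrical extrusion).

    Seed contours drawn on a start slice and slid to an end slice sweep a
    cylinder through the stack; the filled interiors become hard seed voxels.
    Object/background overlap anywhere raises :class:`SeedOverlapError`.
    """
    if not contours:
        raise ValueError("no seed contours given")
    nz, nr, nc = volume.shape
    obj = np.zeros(volume.shape, dtype=bool)
    bkg = np.zeros(volume.shape, dtype=bool)
    for con in contours:
        z0, z1 = con.slice_range
        if not (0 <= z0 <= z1 < nz):
            raise ValueError(f"slice range {con.slice_range} outside volume with {nz} slices")
        v = con.vertices
        if v[:, 0].min() < 0 or v[:, 1].min() < 0 or v[:, 0].max() > nr - 1 or v[:, 1].max() > nc - 1:
            raise ValueError("seed polygon extends outside the image grid")
        _check_simple_polygon(v)
        rr, cc = _fill_polygon(v[:, 0], v[:, 1], shape=(nr, nc))
        target = obj if con.label == "object" else bkg
        target[z0 : z1 + 1, rr, cc] = True
    if not obj.any():
        raise ValueError("no object seed voxels were produced")
    if not bkg.any():
        raise ValueError("no background seed voxels were produced")
    return SeedSet(obj, bkg)  # disjointness enforced by SeedSet


def seeds_from_label_mask(labels: np.ndarray | str | Path) -> SeedSet:
    """Build a SeedSet from an integer label grid or file (0 unlabeled, 1 object, 2 background)."""
    if isinstance(labels, (str, Path)):
        vol = read_volume(Path(labels), None if Path(labels).is_dir() else _infer_format(Path(labels)))
        arr = np.rint(vol.intensities).astype(np.int64)
    else:
        arr = np.rint(np.asarray(labels)).astype(np.int64)
    bad = set(np.unique(arr)) - {0, 1, 2}
    if bad:
        raise ValueError(f"seed label mask contains values other than 0/1/2: {sorted(bad)}")
    return SeedSet(arr == 1, arr == 2)
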