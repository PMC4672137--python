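import numpy as np
import pytest

import swarmcut as sc


@pytest.fixture(scope="session")
def clean_phantom():
    """High-contrast phantom with no blur/noise: ground truth is unambiguous."""
    spec = sc.PhantomSpec(
        shape=(40, 40, 40), organ_delta=200.0, blur_mm=0.0, noise_hu=0.0,
        with_vessels=False, rng_seed=0,
    )
    return sc.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Realistic phantom: 60 HU adjacent-organ contrast, 1 mm blur, 10 HU noise."""
    spec = sc.PhantomSpec(shape=(48, 48, 48), organ_delta=60.0, rng_seed=1)
    return sc.generate_phantom(spec)


@pytest.fixture(scope="session")
def iso_slice_phantom():
    """Near-iso-intense adjacent organ: the invisible-boundary regime, one slab."""
    spec = sc.PhantomSpec(shape=(24, 64, 64), organ_delta=5.0, rng_seed=0)
    return sc.generate_phantom(spec)


def write_dicom_series(directory, volume_hu, row_sp=0.486, col_sp=0.486, z_positions=None):
    """Create a minimal CT DICOM series on disk from a (slices, rows, cols) HU array."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    volume_hu = np.asarray(volume_hu)
    nz = volume_hu.shape[0]
    if z_positions is None:
        z_positions = [float(z) for z in range(nz)]
    series_uid = generate_uid()
    intercept, slope = -1024.0, 1.0
    for z in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [0.0, 0.0, z_positions[z]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [row_sp, col_sp]
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = slope
        ds.Rows, ds.Columns = volume_hu.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        raw = np.round((volume_hu[z] - intercept) / slope).astype(np.uint16)
        ds.PixelData = raw.tobytes()
        ds.save_as(str(directory / f"slice{z:03d}.dcm"), enforce_file_format=True)
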