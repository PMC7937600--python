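"""Shared fixtures: tiny synthetic volumes written programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ibrad.imaging import ROIMask, ScanImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_pair(rng):
    """A 4-slice 24x24 volume with an off-centre blob mask."""
    spacing = (0.7, 0.7, 3.0)
    vox = rng.normal(100.0, 12.0, size=(4, 24, 24))
    img = ScanImage(vox, spacing, patient_id="T0", cohort="1.5T")
    mask = np.zeros_like(vox, dtype=bool)
    zz, rr, cc = np.ogrid[:4, :24, :24]
    mask[((zz - 1.5) / 1.6) ** 2 + ((rr - 12) / 7) ** 2 + ((cc - 11) / 6) ** 2 <= 1.0] = True
    return img, ROIMask(mask, spacing)


def write_dicom_series(directory, volume, row_mm, col_mm, slice_mm, series_uid=None, pixel_spacings=None):
    """Minimal CT-like DICOM series writer for loader tests."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = series_uid or generate_uid()
    paths = []
    for k in range(volume.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        path = str(directory / f"slice_{k:03d}.dcm")
        ds = FileDataset(path, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * slice_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        sp = pixel_spacings[k] if pixel_spacings else (row_mm, col_mm)
        ds.PixelSpacing = [sp[0], sp[1]]
        ds.SliceThickness = slice_mm
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = volume[k].astype(np.uint16).tobytes()
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
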