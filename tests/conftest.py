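"""Shared fixtures: synthetic DICOM writing and cached phantom stacks."""

from __future__ import annotations

import numpy as np
import pytest

from lungcad import PhantomConfig, generate_stack


def write_test_dicom(path, array16, instance_number=None, patient_name="Doe^Jane"):
    """Write a minimal single-frame 16-bit grayscale DICOM for tests."""
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import (
        ExplicitVRLittleEndian,
        SecondaryCaptureImageStorage,
        generate_uid,
    )

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = patient_name
    ds.PatientID = "PID-0001"
    ds.PatientBirthDate = "19700101"
    ds.Modality = "CT"
    arr = np.asarray(array16, dtype=np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if instance_number is not None:
        ds.InstanceNumber = instance_number
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


@pytest.fixture
def dicom_writer():
    return write_test_dicom


_PHANTOM_CACHE: dict = {}


def phantom(seed: int, **overrides):
    """Cached phantom generation so several tests can share one stack."""
    key = (seed, tuple(sorted(overrides.items())))
    if key not in _PHANTOM_CACHE:
        _PHANTOM_CACHE[key] = generate_stack(PhantomConfig(seed=seed, **overrides))
    return _PHANTOM_CACHE[key]


@pytest.fixture
def default_phantom():
    """One default phantom stack with ground truth (seed 1)."""
    return phantom(1)
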