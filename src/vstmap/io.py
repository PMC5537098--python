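"""Readers and writers for images, masks and phantom output.

Supported image inputs: single-frame DICOM (rescale slope/intercept
applied, yielding HU), and 8/16-bit PNG/TIFF.  Masks: binary PNG/TIFF
(any nonzero pixel is foreground) or a CSV pixel list with ``row,col``
columns.  Phantom images are written as signed 16-bit TIFF (PNG cannot
hold signed HU-like values) or, on request, as a minimal secondary-capture
DICOM.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


def read_image(path: str | Path) -> np.ndarray:
    """Load a 2-D intensity image; DICOM gets its rescale applied."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"} or _looks_like_dicom(path):
        return _read_dicom(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse an accidental colour image
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame 2-D image")
    return arr


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame DICOM")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a binary mask from an image file or a ``row,col`` CSV pixel list."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if shape is None:
            raise ValueError("a CSV pixel-list mask needs the image shape")
        df = pd.read_csv(path)
        mask = np.zeros(shape, bool)
        mask[df.iloc[:, 0].to_numpy(int), df.iloc[:, 1].to_numpy(int)] = True
        return mask
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write HU-like pixels as int16 TIFF, uint8/16 PNG, or DICOM by suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        _write_dicom(path, pixels)
    elif suffix == ".png":
        lo = int(pixels.min())
        if lo < 0:
            raise ValueError(
                "PNG cannot store negative intensities; use TIFF or DICOM"
            )
        iio.imwrite(path, pixels.astype(np.uint16))
    else:
        iio.imwrite(path, pixels.astype(np.int16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def _write_dicom(path: Path, pixels: np.ndarray) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1
    ds.RescaleIntercept = 0
    ds.PixelData = pixels.astype(np.int16).tobytes()
    pydicom.dcmwrite(path, ds, little_endian=True, implicit_vr=False)
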