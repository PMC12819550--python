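"""Axial CT volume container and image I/O (NIfTI, DICOM series).

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` — slice, row, column;
* the z index increases caudally, so slice 0 is the most cranial one and
  needle tips (which sit cranially) have the smallest z coordinates;
* all coordinates exchanged between functions are physical millimetres of
  voxel *centers*: ``p = origin + index * spacing``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "save_nifti", "load_nifti", "save_dicom_series", "load_dicom_series"]


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units on a regular axial grid.

    Parameters
    ----------
    voxels:
        HU values, shape ``(nz, ny, nx)``.
    spacing:
        ``(dz, dy, dx)`` in mm; the clinical default is ``(2.0, 0.3, 0.3)``.
    origin:
        Physical ``(z, y, x)`` in mm of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 0.3, 0.3)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    #: z index increases caudally; the tip side is the low-z side.
    z_orientation: str = "caudal-increasing"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if self.voxels.shape[0] < 2:
            raise ValueError("a CT volume needs at least 2 slices")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def z_coords(self) -> np.ndarray:
        """Physical z of every slice center, cranial to caudal."""
        nz = self.voxels.shape[0]
        return self.origin[0] + self.spacing[0] * np.arange(nz)

    def slice_index(self, z: float) -> int:
        """Index of the slice whose center is nearest to physical ``z``."""
        idx = int(round((z - self.origin[0]) / self.spacing[0]))
        if idx < 0 or idx >= self.voxels.shape[0]:
            raise IndexError(f"z = {z} mm falls outside the volume")
        return idx

    def slice_z(self, index: int) -> float:
        return float(self.origin[0] + self.spacing[0] * index)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinates of pixel centers in one slice."""
        ny, nx = self.voxels.shape[1:]
        y = self.origin[1] + self.spacing[1] * np.arange(ny)
        x = self.origin[2] + self.spacing[2] * np.arange(nx)
        return y, x

    def contains_yx(self, y: float, x: float) -> bool:
        yc, xc = self.pixel_centers()
        return bool(yc[0] <= y <= yc[-1] and xc[0] <= x <= xc[-1])


def save_nifti(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz); HU stored as float32."""
    import nibabel as nib

    dz, dy, dx = volume.spacing
    # nibabel expects (i, j, k) = (x, y, z) ordering
    data = np.ascontiguousarray(np.transpose(volume.voxels, (2, 1, 0)).astype(np.float32))
    affine = np.diag([dx, dy, dz, 1.0]).astype(float)
    affine[:3, 3] = [volume.origin[2], volume.origin[1], volume.origin[0]]
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, os.fspath(path))


def load_nifti(path: str | os.PathLike) -> CTVolume:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    voxels = np.transpose(data, (2, 1, 0))
    aff = img.affine
    spacing = (float(aff[2, 2]), float(aff[1, 1]), float(aff[0, 0]))
    origin = np.array([aff[2, 3], aff[1, 3], aff[0, 3]], dtype=float)
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin)


def save_dicom_series(volume: CTVolume, directory: str | os.PathLike) -> list[str]:
    """Write a volume as a CT DICOM series, one file per axial slice.

    HU values are rounded to signed 16-bit integers and stored with
    RescaleSlope 1 / RescaleIntercept 0, so integer-valued volumes round-trip
    exactly.  ImagePositionPatient/PixelSpacing/SliceThickness carry the grid
    geometry in the package's (z, y, x) mm convention.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    dz, dy, dx = volume.spacing
    paths = []
    for k in range(volume.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "SYN"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [float(volume.origin[2]), float(volume.origin[1]), volume.slice_z(k)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(dy), float(dx)]  # row spacing, column spacing
        ds.SliceThickness = float(dz)
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.round(volume.voxels[k]).astype(np.int16).tobytes()
        path = os.path.join(directory, f"slice_{k:04d}.dcm")
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def load_dicom_series(directory: str | os.PathLike) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(os.fspath(directory), f)
        for f in os.listdir(directory)
        if f.endswith(".dcm")
    )
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(arr)
    voxels = np.stack(slices)
    first = datasets[0]
    dz = (
        float(datasets[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
        if len(datasets) > 1
        else float(first.SliceThickness)
    )
    dy, dx = (float(v) for v in first.PixelSpacing)
    origin = np.array(
        [float(first.ImagePositionPatient[2]), float(first.ImagePositionPatient[1]), float(first.ImagePositionPatient[0])]
    )
    return CTVolume(voxels=voxels, spacing=(dz, dy, dx), origin=origin)
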