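"""LGE volume I/O and per-target DICOM treatment datasets.

Reading accepts either a directory of single-frame DICOM files or a NIfTI
file and yields an :class:`~cartoplan.image.ImageVolume` in DICOM patient
(LPS) coordinates with slices sorted along the slice normal.

Each planned injection target is exported as its own DICOM *treatment
dataset*: a secondary-capture series in the geometry of the base volume, in
which the target is voxelized as a filled sphere at maximal intensity and a
subsampled endocardial point cloud at unit intensity — a viewer-agnostic
encoding any fusion workstation can overlay.  A JSON sidecar per target
carries the exact millimetre coordinates, sector label and needle depth; the
sidecar, not the voxelization, is the authoritative record.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from cartoplan.cardiac_maps import EndoSurfaceMap
from cartoplan.image import ImageVolume
from cartoplan.planner import TargetPlan


# -- reading ------------------------------------------------------------


def _read_dicom_dir(path: Path) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM clutter
        datasets.append((f, ds))
    if not datasets:
        raise ValueError(f"no DICOM files found in {path}")

    ref = datasets[0][1]
    for f, ds in datasets:
        for tag in ("ImageOrientationPatient", "ImagePositionPatient", "PixelSpacing"):
            if tag not in ds:
                raise ValueError(f"{f}: missing {tag}")
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float),
                           np.asarray(ref.ImageOrientationPatient, dtype=float), atol=1e-6):
            raise ValueError(f"{f}: slice orientation differs from the rest of the series")
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float),
                           np.asarray(ref.PixelSpacing, dtype=float), atol=1e-9):
            raise ValueError(f"{f}: pixel spacing differs from the rest of the series")

    iop = np.asarray(ref.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]          # along increasing col / row
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda fd: float(np.dot(np.asarray(
        fd[1].ImagePositionPatient, dtype=float), normal)))

    slices = []
    positions = []
    for _, ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
        positions.append(np.asarray(ds.ImagePositionPatient, dtype=float))
    data = np.stack(slices)

    if len(positions) > 1:
        slice_spacing = float(np.dot(positions[1] - positions[0], normal))
        slice_dir = (positions[1] - positions[0]) / np.linalg.norm(positions[1] - positions[0])
    else:
        slice_spacing = float(getattr(ref, "SliceThickness", 1.0))
        slice_dir = normal
    ps = np.asarray(ref.PixelSpacing, dtype=float)  # [row, col]
    spacing = np.array([ps[1], ps[0], abs(slice_spacing)])
    orientation = np.column_stack([row_dir, col_dir, slice_dir])
    return ImageVolume(data=data, spacing=spacing, origin=positions[0],
                       orientation=orientation)


def read_lge_series(path) -> ImageVolume:
    """Read an LGE volume from a DICOM directory or a NIfTI file.

    Returns an :class:`ImageVolume` (voxels + voxel->patient affine) in LPS
    mm with slices sorted along the slice normal.  Mixed in-plane
    orientations or missing geometry tags raise an error naming the
    offending file.
    """
    p = Path(path)
    if p.is_dir():
        return _read_dicom_dir(p)
    if p.suffix in (".nii", ".gz") or p.name.endswith(".nii.gz"):
        return ImageVolume.from_nifti(p)
    raise ValueError(f"{path}: expected a DICOM directory or a NIfTI file")


# -- writing ------------------------------------------------------------


def _integer_representable(data: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(data)) and np.all(data >= 0) and np.all(data <= 65535)
                and np.allclose(data, np.round(data)))


def save_dicom_series(vol: ImageVolume, out_dir, series_description: str = "cartoplan",
                      series_number: int = 1) -> list[Path]:
    """Write an :class:`ImageVolume` as a directory of single-frame DICOM files.

    Non-negative integer-valued volumes are stored losslessly as uint16;
    arbitrary float volumes are linearly rescaled into uint16 with the slope
    and intercept recorded (16-bit quantisation).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data, dtype=float)
    if _integer_representable(data):
        slope, intercept = 1.0, 0.0
        stored = np.round(data).astype(np.uint16)
    else:
        lo, hi = float(np.min(data)), float(np.max(data))
        slope = (hi - lo) / 65535.0 if hi > lo else 1.0
        intercept = lo
        stored = np.round((data - intercept) / slope).astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    now = datetime.datetime.now()
    row_dir = vol.orientation[:, 0]
    col_dir = vol.orientation[:, 1]
    files: list[Path] = []
    for k in range(vol.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = series_number
        ds.InstanceNumber = k + 1
        ds.SeriesDescription = series_description
        ds.Modality = "OT"
        ds.PatientName = "cartoplan^phantom"
        ds.PatientID = "cartoplan"
        ds.ContentDate = now.strftime("%Y%m%d")
        ds.ContentTime = now.strftime("%H%M%S")
        ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]  # [row, col]
        ds.SliceThickness = float(vol.spacing[2])
        pos = vol.voxel_to_world([0.0, 0.0, float(k)])
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.ImageOrientationPatient = [float(v) for v in np.concatenate([row_dir, col_dir])]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = np.ascontiguousarray(stored[k]).tobytes()
        fname = out / f"slice_{k:03d}.dcm"
        ds.save_as(str(fname), enforce_file_format=True)
        files.append(fname)
    return files


def _voxelize_sphere(vol_shape: tuple[int, int, int], geometry: ImageVolume,
                     center: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``radius`` of ``center``."""
    nz, ny, nx = vol_shape
    cidx = geometry.world_to_voxel(center)  # (col, row, slice)
    r_vox = radius / np.min(geometry.spacing)
    lo = np.maximum(np.floor(cidx - r_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(cidx + r_vox + 1).astype(int),
                    np.array([nx - 1, ny - 1, nz - 1]))
    mask = np.zeros(vol_shape, dtype=bool)
    cols = np.arange(lo[0], hi[0] + 1)
    rows = np.arange(lo[1], hi[1] + 1)
    slcs = np.arange(lo[2], hi[2] + 1)
    if len(cols) == 0 or len(rows) == 0 or len(slcs) == 0:
        return mask
    cc, rr, ss = np.meshgrid(cols, rows, slcs, indexing="ij")
    idx = np.column_stack([cc.ravel(), rr.ravel(), ss.ravel()]).astype(float)
    pts = np.atleast_2d(geometry.voxel_to_world(idx))
    inside = np.linalg.norm(pts - center, axis=1) <= radius
    mask[ss.ravel()[inside], rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def write_treatment_datasets(plan: TargetPlan, emap: EndoSurfaceMap,
                             geometry: ImageVolume, out_dir,
                             marker_radius: float = 2.0,
                             endo_subsample: int = 4,
                             base_series_reference: str = "",
                             config_hash: str = "") -> list[Path]:
    """Write one DICOM treatment series plus a JSON sidecar per target.

    The series volume copies the base geometry; endocardial points are
    voxelized at intensity 1 and the target as a filled sphere (default
    radius 2 mm) at intensity 1000.  Raises when a target falls outside the
    volume bounds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    endo_pts = emap.vertices[::endo_subsample]
    timestamp = datetime.datetime.now().isoformat(timespec="seconds")
    written: list[Path] = []
    for i, target in enumerate(plan.targets, start=1):
        if not geometry.contains_point(target.position):
            raise ValueError(f"target {i} at {target.position} lies outside the volume")
        marker = np.zeros(geometry.data.shape, dtype=float)
        vox = np.round(np.atleast_2d(geometry.world_to_voxel(endo_pts))).astype(int)
        ok = np.all(vox >= 0, axis=1) & (vox[:, 0] < marker.shape[2]) \
            & (vox[:, 1] < marker.shape[1]) & (vox[:, 2] < marker.shape[0])
        marker[vox[ok, 2], vox[ok, 1], vox[ok, 0]] = 1.0
        sphere = _voxelize_sphere(marker.shape, geometry, target.position, marker_radius)
        marker[sphere] = 1000.0
        series_dir = out / f"target_{i:02d}"
        save_dicom_series(
            ImageVolume(data=marker, spacing=geometry.spacing, origin=geometry.origin,
                        orientation=geometry.orientation),
            series_dir, series_description=f"treatment target {i:02d}", series_number=i)
        sidecar = out / f"target_{i:02d}.json"
        payload = dict(target.to_dict())
        payload.update({
            "target_number": i,
            "marker_radius_mm": marker_radius,
            "base_series_reference": base_series_reference,
            "provenance": {"config_hash": config_hash, "timestamp": timestamp},
        })
        with open(sidecar, "w") as fh:
            json.dump(payload, fh, indent=1)
        written.append(series_dir)
        written.append(sidecar)
    return written


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
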