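"""In-memory image volume with patient-space (LPS, mm) geometry.

The container is deliberately minimal: a voxel array indexed ``[slice, row,
col]`` plus the affine ingredients DICOM carries (pixel spacing, image
position, direction cosines).  NIfTI I/O converts between RAS (NIfTI) and LPS
(DICOM) at the boundary so that everything inside the package speaks DICOM
patient coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: diag(-1,-1,1): LPS <-> RAS flips the first two patient axes.
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


@dataclass
class ImageVolume:
    """A 3-D intensity volume with its voxel-to-patient mapping.

    Parameters
    ----------
    data
        Voxel array of shape ``(n_slices, n_rows, n_cols)``.
    spacing
        ``(col, row, slice)`` spacing in mm.
    origin
        Patient-space (LPS) position in mm of the centre of voxel
        ``(slice=0, row=0, col=0)``.
    orientation
        3x3 matrix whose *columns* are the patient-space unit direction of
        increasing column, row and slice index, respectively.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive numbers (col, row, slice) in mm")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 direction-cosine matrix")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def affine(self) -> np.ndarray:
        """4x4 affine mapping ``(col, row, slice)`` voxel indices to LPS mm."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map ``(col, row, slice)`` (possibly fractional) indices to LPS mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        pts = idx @ (self.orientation * self.spacing[np.newaxis, :]).T + self.origin
        return pts if pts.shape[0] > 1 else pts[0]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map LPS mm points to fractional ``(col, row, slice)`` indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        m = self.orientation * self.spacing[np.newaxis, :]
        idx = np.linalg.solve(m, (pts - self.origin).T).T
        return idx if idx.shape[0] > 1 else idx[0]

    def contains_point(self, pt: np.ndarray) -> bool:
        """Whether an LPS point falls inside the voxel lattice (half-voxel slack)."""
        cidx = self.world_to_voxel(pt)
        limits = np.array([self.data.shape[2], self.data.shape[1], self.data.shape[0]])
        return bool(np.all(cidx >= -0.5) and np.all(cidx <= limits - 0.5))

    def slice_z(self, k: int) -> float:
        """Patient z of slice ``k`` (axis-aligned volumes only)."""
        return float(self.voxel_to_world([0.0, 0.0, float(k)])[2])

    # -- NIfTI boundary ------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        # nibabel wants (x=col, y=row, z=slice) fastest-first and an RAS affine
        arr = np.ascontiguousarray(np.transpose(self.data, (2, 1, 0)))
        aff = self.affine.copy()
        aff[:3, :] = _LPS_TO_RAS @ aff[:3, :]
        return nib.Nifti1Image(arr.astype(np.float32), aff)

    def save_nifti(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path_or_img) -> "ImageVolume":
        img = path_or_img if isinstance(path_or_img, nib.Nifti1Image) else nib.load(str(path_or_img))
        aff = np.asarray(img.affine, dtype=float)
        aff_lps = aff.copy()
        aff_lps[:3, :] = _LPS_TO_RAS @ aff_lps[:3, :]
        m = aff_lps[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        orientation = m / spacing[np.newaxis, :]
        data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
        return cls(data=np.asarray(data), spacing=spacing, origin=aff_lps[:3, 3],
                   orientation=orientation)
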