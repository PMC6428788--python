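"""Full-width-at-half-maximum (FWHM) infarct segmentation.

Scar is segmented inside a given myocardial mask by thresholding at half of
the myocardial enhancement range: ``T = I_min + 0.5 * (I_max - I_min)``
computed over myocardial pixels.  The half-maximum is referenced to the
myocardial minimum (rather than ``0.5 * I_max``) because that variant is
robust to global intensity scaling and offsets; the pure half-of-maximum
reference is available via ``reference="max"``.  The reference statistics are
taken per slice by default; a per-volume threshold is available via
:func:`segment_volume`.

Connected components smaller than ``min_component_px`` pixels are removed to
suppress isolated noise pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.draw import polygon2mask

from cartoplan.cardiac_maps import ContourStack

logger = logging.getLogger(__name__)


@dataclass
class MyocardialSlice:
    """Intensity slice plus the myocardial mask segmentation is restricted to."""

    intensities: np.ndarray
    myo_mask: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.myo_mask = np.asarray(self.myo_mask, dtype=bool)
        if self.intensities.shape != self.myo_mask.shape:
            raise ValueError("intensities and myo_mask must have the same shape")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass
class ScarSegmentation:
    """Per-slice binary scar masks on a common in-plane pixel grid.

    ``origin`` is the patient-space ``(x, y)`` mm of pixel ``(row=0, col=0)``'s
    centre and ``spacing`` the isotropic in-plane pixel size; both are needed
    to sample the masks along mm-space chords.
    """

    masks: list[np.ndarray]
    thresholds: list[float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    spacing: float = 1.0
    zs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        self.origin = np.asarray(self.origin, dtype=float)


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 1 or not mask.any():
        return mask
    labels = measure.label(mask, connectivity=1)
    keep = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        if region.area >= min_px:
            keep[labels == region.label] = True
    return keep


def fwhm_threshold(values: np.ndarray, reference: str = "min") -> float:
    """Half-maximum threshold over myocardial intensities.

    ``reference="min"``: T = min + 0.5 (max - min);  ``reference="max"``:
    T = 0.5 max.
    """
    vmax = float(np.max(values))
    if reference == "min":
        vmin = float(np.min(values))
        return vmin + 0.5 * (vmax - vmin)
    if reference == "max":
        return 0.5 * vmax
    raise ValueError(f"unknown FWHM reference {reference!r}")


def fwhm_segment(myo_slice: MyocardialSlice, min_component_px: int = 5,
                 reference: str = "min",
                 threshold: float | None = None) -> tuple[np.ndarray, float]:
    """Segment scar in one slice; returns ``(scar_mask, threshold_used)``.

    A degenerate slice (all myocardial intensities equal) yields an empty
    scar mask with a logged warning rather than an error.  An explicit
    ``threshold`` overrides the per-slice statistic (used by the per-volume
    mode).
    """
    if not myo_slice.myo_mask.any():
        raise ValueError("myocardial mask is empty")
    values = myo_slice.intensities[myo_slice.myo_mask]
    if threshold is None:
        if np.max(values) == np.min(values):
            logger.warning("degenerate slice: uniform myocardial intensity %g; "
                           "returning empty scar mask", values[0])
            return np.zeros_like(myo_slice.myo_mask), float(values[0])
        threshold = fwhm_threshold(values, reference)
    scar = myo_slice.myo_mask & (myo_slice.intensities >= threshold)
    scar = _remove_small(scar, min_component_px)
    return scar, float(threshold)


def myocardial_masks(stack: ContourStack, shape: tuple[int, int], origin: np.ndarray,
                     spacing: float) -> list[np.ndarray]:
    """Rasterize the region between endo and epi contours per slice (even-odd).

    A pixel is myocardial when its centre lies inside the epicardial polygon
    and outside the endocardial one.
    """
    origin = np.asarray(origin, dtype=float)
    masks = []
    for s in stack.slices:
        def to_rc(poly):
            rows = (poly[:, 1] - origin[1]) / spacing
            cols = (poly[:, 0] - origin[0]) / spacing
            return np.column_stack([rows, cols])

        inside_epi = polygon2mask(shape, to_rc(s.epi))
        inside_endo = polygon2mask(shape, to_rc(s.endo))
        masks.append(inside_epi & ~inside_endo)
    return masks


def segment_volume(intensities: list[np.ndarray] | np.ndarray,
                   myo_masks: list[np.ndarray],
                   pixel_spacing: float,
                   origin: np.ndarray = (0.0, 0.0),
                   zs: np.ndarray | None = None,
                   min_component_px: int = 5,
                   reference: str = "min",
                   per_volume: bool = False) -> ScarSegmentation:
    """FWHM segmentation of a whole stack of slices.

    With ``per_volume=True`` a single threshold computed over all myocardial
    voxels is applied to every slice; the default recomputes the reference
    statistics per slice.
    """
    slices = [MyocardialSlice(img, m, pixel_spacing) for img, m in zip(intensities, myo_masks)]
    shared: float | None = None
    if per_volume:
        values = np.concatenate([s.intensities[s.myo_mask] for s in slices])
        if np.max(values) == np.min(values):
            logger.warning("degenerate volume: uniform myocardial intensity; empty scar")
            return ScarSegmentation(masks=[np.zeros_like(s.myo_mask) for s in slices],
                                    thresholds=[float(values[0])] * len(slices),
                                    origin=origin, spacing=pixel_spacing, zs=zs)
        shared = fwhm_threshold(values, reference)
    masks, thresholds = [], []
    for s in slices:
        scar, thr = fwhm_segment(s, min_component_px, reference, threshold=shared)
        masks.append(scar)
        thresholds.append(thr)
    return ScarSegmentation(masks=masks, thresholds=thresholds, origin=origin,
                            spacing=pixel_spacing, zs=zs)
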