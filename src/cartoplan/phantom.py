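"""Synthetic left-ventricle LGE phantoms with analytic ground truth.

The phantom is a stack of circular annuli (optionally tapered toward the
apex): per slice an endocardial radius, a wall thickness, and an angular scar
wedge whose *transmurality profile* prescribes which innermost fraction of
each radial wall chord is infarcted.  Voxel intensities are
``remote_intensity`` in viable myocardium and ``scar_intensity`` in scar
(hyperenhancement), with zero-mean Gaussian noise; the background (blood pool
and outside the epicardium) sits below the remote intensity.  Every ground
truth quantity — contours, scar mask, per-angle transmurality and wall
thickness — is known analytically, so each downstream stage of the planning
pipeline can be tested without any external data.

Coordinates are right-handed patient space in mm: slices apex->base along +z,
angles counter-clockwise from +x in-slice.  The default scar is an
antero-septal wedge straddling the septal/anterior boundary, mirroring the
infarct model the planner is meant for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from cartoplan.cardiac_maps import ContourStack, SliceContours
from cartoplan.image import ImageVolume
from cartoplan.registration import RigidTransform
from cartoplan.scarseg import ScarSegmentation

Profile = Callable[[np.ndarray, int], np.ndarray]


def graded_wedge_profile(theta_range: tuple[float, float],
                         shoulder: tuple[float, float] = (0.6, 0.3)) -> Profile:
    """Piecewise-linear transmurality: 1 at the wedge core, 0 at its edges.

    ``shoulder = (position, value)`` bends the ramp: at ``position`` (fraction
    of the half-width from the edge toward the core) the profile reaches
    ``value``, rising linearly on either side.  The default gives a shallow
    low-transmurality tail at the wedge edges — a wide border zone flanking a
    dense core, as in a reperfused infarct — rather than a knife-edge.  Set
    ``shoulder=(0.5, 0.5)`` for a plain triangular ramp.
    """
    t1, t2 = theta_range
    width = (t2 - t1) % 360.0 or 360.0
    half = 0.5 * width
    spos, sval = shoulder
    if not (0.0 < spos < 1.0 and 0.0 <= sval <= 1.0):
        raise ValueError("shoulder must be (position in (0,1), value in [0,1])")

    def profile(theta_deg: np.ndarray, slice_index: int) -> np.ndarray:
        offset = np.mod(np.asarray(theta_deg, dtype=float) - t1, 360.0)
        u = np.clip(1.0 - np.abs(offset - half) / half, 0.0, 1.0)  # 0 edge, 1 core
        return np.where(u <= spos, sval * u / spos,
                        sval + (1.0 - sval) * (u - spos) / (1.0 - spos))

    return profile


def constant_profile(value: float) -> Profile:
    """Uniform transmurality over the whole wedge."""

    def profile(theta_deg: np.ndarray, slice_index: int) -> np.ndarray:
        return np.full_like(np.asarray(theta_deg, dtype=float), float(value))

    return profile


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise parameters of the synthetic LV.

    ``endo_radius`` and ``wall_thickness`` may be scalars or per-slice
    (apex->base) profiles.  ``transmurality_profile`` maps (angle degrees,
    slice index) to the infarcted wall fraction in [0, 1]; it is evaluated
    only inside ``scar_theta_range``.  Defaults give an 8-slice ventricle,
    20 mm endocardial radius, 10 mm wall, a 60 degree antero-septal wedge
    with transmurality graded from fully transmural at the core to 0 at the
    edges, 3:1 scar contrast and 10% Gaussian noise.

    ``center_drift`` shifts each slice centre by that in-plane vector per
    slice (apex->base), emulating the oblique long axis of the ventricle in
    patient coordinates, and ``apex_taper`` shrinks a scalar ``endo_radius``
    linearly toward the apex (slice 0 radius = ``(1 - apex_taper) x base``).
    Together they break the rotational and flip symmetries of a straight
    stack of equal circles — without them the epicardial surface would be a
    surface of revolution and rigid registration about the long axis would
    be ill-posed, which neither a real heart nor a useful test geometry is.
    Set drift ``(0, 0)`` and taper 0 for exactly concentric equal slices.
    ``apex_taper`` is ignored when ``endo_radius`` is given per slice.
    """

    n_slices: int = 8
    slice_spacing: float = 5.0
    endo_radius: float | np.ndarray = 20.0
    wall_thickness: float | np.ndarray = 10.0
    scar_theta_range: tuple[float, float] = (60.0, 120.0)
    transmurality_profile: Profile | None = None
    remote_intensity: float = 100.0
    scar_intensity: float = 300.0
    noise_sd: float = 10.0
    pixel_spacing: float = 0.8
    center_drift: tuple[float, float] = (3.5, 1.75)
    apex_taper: float = 0.5
    seed: int = 0
    septal_direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")
        if self.slice_spacing <= 0 or self.pixel_spacing <= 0:
            raise ValueError("spacings must be positive")
        r = np.broadcast_to(np.asarray(self.endo_radius, dtype=float), (self.n_slices,))
        w = np.broadcast_to(np.asarray(self.wall_thickness, dtype=float), (self.n_slices,))
        if np.any(r <= 0) or np.any(w <= 0):
            raise ValueError("endo_radius and wall_thickness must be positive")
        width = (self.scar_theta_range[1] - self.scar_theta_range[0])
        if width > 360.0:
            raise ValueError("scar wedge cannot exceed 360 degrees")
        if self.scar_intensity <= self.remote_intensity:
            raise ValueError("scar_intensity must exceed remote_intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.apex_taper < 1.0):
            raise ValueError("apex_taper must be in [0, 1)")

    @property
    def endo_radii(self) -> np.ndarray:
        r = np.asarray(self.endo_radius, dtype=float)
        if r.ndim == 0:
            scale = np.linspace(1.0 - self.apex_taper, 1.0, self.n_slices)
            return float(r) * scale
        return np.broadcast_to(r, (self.n_slices,)).copy()

    @property
    def wall_thicknesses(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.wall_thickness, dtype=float),
                               (self.n_slices,)).copy()

    @property
    def profile(self) -> Profile:
        if self.transmurality_profile is not None:
            return self.transmurality_profile
        return graded_wedge_profile(self.scar_theta_range)


@dataclass
class PhantomTruth:
    """Analytic ground truth emitted alongside the intensity volume."""

    contours: ContourStack
    scar_mask: np.ndarray          # bool (n_slices, ny, nx)
    myo_mask: np.ndarray           # bool (n_slices, ny, nx)
    transmurality_true: np.ndarray  # percent, (n_slices, n_angles)
    wall_thickness_true: np.ndarray  # mm, (n_slices, n_angles)
    theta_grid: np.ndarray         # degrees, (n_angles,)
    septal_direction: np.ndarray   # unit 2-vector in-slice
    grid_origin: np.ndarray = field(default=None)  # (x, y) mm of pixel (0, 0)
    pixel_spacing: float = 1.0

    def scar_segmentation(self) -> ScarSegmentation:
        """The true scar as a :class:`ScarSegmentation` (oracle for tests)."""
        return ScarSegmentation(
            masks=[self.scar_mask[k] for k in range(self.scar_mask.shape[0])],
            thresholds=[np.nan] * self.scar_mask.shape[0],
            origin=self.grid_origin, spacing=self.pixel_spacing,
            zs=self.contours.zs)

    def myocardial_masks(self) -> list[np.ndarray]:
        return [self.myo_mask[k] for k in range(self.myo_mask.shape[0])]


def _in_wedge(theta_deg: np.ndarray, theta_range: tuple[float, float]) -> np.ndarray:
    t1, t2 = theta_range
    width = (t2 - t1) % 360.0
    if width == 0.0 and t2 != t1:
        width = 360.0
    return np.mod(theta_deg - t1, 360.0) < width


def generate_phantom(spec: PhantomSpec,
                     n_contour_points: int = 360,
                     margin: float = 8.0) -> tuple[ImageVolume, PhantomTruth]:
    """Generate the intensity volume and its exact ground truth.

    Voxels are classified by their centre against the analytic annulus/wedge
    geometry; the same classification defines the truth masks, so with zero
    noise the intensity image and the truth are mutually consistent to the
    pixel.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    radii = spec.endo_radii
    walls = spec.wall_thicknesses
    profile = spec.profile

    drift = np.asarray(spec.center_drift, dtype=float)
    centers = np.outer(np.arange(spec.n_slices, dtype=float), drift)
    extent = 2.0 * (float(np.max(radii + walls)) + float(np.max(np.abs(centers), initial=0.0))
                    + margin)
    npix = int(np.ceil(extent / spec.pixel_spacing))
    half = (npix - 1) / 2.0 * spec.pixel_spacing
    xs = -half + spec.pixel_spacing * np.arange(npix)
    X, Y = np.meshgrid(xs, xs)          # rows = y, cols = x

    theta_grid = np.arange(n_contour_points) * (360.0 / n_contour_points)
    background = 0.3 * spec.remote_intensity

    data = np.empty((spec.n_slices, npix, npix))
    scar_mask = np.zeros_like(data, dtype=bool)
    myo_mask = np.zeros_like(data, dtype=bool)
    slices = []
    trans_true = np.zeros((spec.n_slices, n_contour_points))
    wt_true = np.zeros_like(trans_true)

    for k in range(spec.n_slices):
        r, w = radii[k], walls[k]
        cx, cy = centers[k]
        rho = np.hypot(X - cx, Y - cy)
        theta = np.degrees(np.mod(np.arctan2(Y - cy, X - cx), 2 * np.pi))
        wedge = _in_wedge(theta, spec.scar_theta_range)
        p_grid = np.clip(np.where(wedge, profile(theta, k), 0.0), 0.0, 1.0)
        myo = (rho >= r) & (rho <= r + w)
        scar = myo & wedge & (p_grid > 0) & (rho <= r + p_grid * w)
        img = np.full((npix, npix), background)
        img[myo] = spec.remote_intensity
        img[scar] = spec.scar_intensity
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        data[k] = img
        scar_mask[k] = scar
        myo_mask[k] = myo

        ang = np.radians(theta_grid)
        unit = np.column_stack([np.cos(ang), np.sin(ang)])
        slices.append(SliceContours(z=k * spec.slice_spacing,
                                    endo=centers[k] + r * unit,
                                    epi=centers[k] + (r + w) * unit))
        p_line = np.clip(np.where(_in_wedge(theta_grid, spec.scar_theta_range),
                                  profile(theta_grid, k), 0.0), 0.0, 1.0)
        trans_true[k] = 100.0 * p_line
        wt_true[k] = w

    volume = ImageVolume(
        data=data,
        spacing=np.array([spec.pixel_spacing, spec.pixel_spacing, spec.slice_spacing]),
        origin=np.array([-half, -half, 0.0]),
    )
    truth = PhantomTruth(
        contours=ContourStack(slices=slices),
        scar_mask=scar_mask,
        myo_mask=myo_mask,
        transmurality_true=trans_true,
        wall_thickness_true=wt_true,
        theta_grid=theta_grid,
        septal_direction=np.asarray(spec.septal_direction, dtype=float)
        / np.linalg.norm(spec.septal_direction),
        grid_origin=np.array([-half, -half]),
        pixel_spacing=spec.pixel_spacing,
    )
    return volume, truth


def epicardial_surface_points(truth: PhantomTruth, points_per_slice: int = 300) -> np.ndarray:
    """Sample the epicardial surface of the truth geometry as a 3-D point cloud."""
    from cartoplan import _poly

    pts = []
    for s in truth.contours.slices:
        ring = _poly.resample_ring(s.epi, points_per_slice)
        pts.append(np.column_stack([ring, np.full(len(ring), s.z)]))
    return np.vstack(pts)


def generate_ra_cloud(truth: PhantomTruth, transform: RigidTransform,
                      noise_sd: float = 0.0, keep_fraction: float = 1.0,
                      seed: int = 0,
                      points_per_slice: int = 300) -> tuple[np.ndarray, RigidTransform]:
    """Emulate an interventional 3-D epicardial surface reconstruction.

    Epicardial surface samples of the phantom are moved by ``transform``
    (the unknown patient pose the registration stage must recover), jittered
    with isotropic Gaussian noise and randomly subsampled to ``keep_fraction``.
    The ground-truth transform is returned alongside the cloud for testing.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pts = epicardial_surface_points(truth, points_per_slice)
    n_keep = int(np.floor(keep_fraction * len(pts)))
    if n_keep < 10:
        raise ValueError(f"keep_fraction leaves only {n_keep} points (<10)")
    idx = np.sort(rng.choice(len(pts), size=n_keep, replace=False))
    cloud = transform.apply(pts[idx])
    if noise_sd > 0:
        cloud = cloud + rng.normal(0.0, noise_sd, size=cloud.shape)
    return cloud, transform
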