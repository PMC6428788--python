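"""Endocardial surface mesh and per-vertex wall thickness / infarct transmurality.

The geometric backbone is a :class:`ContourStack`: ordered endo- and
epicardial contours per short-axis slice, in patient coordinates (mm).  The
endocardial contours are resampled to a fixed number of equal-arc-length
points per slice and stitched into a tube mesh; wall thickness (WT) and
infarct transmurality are then computed per vertex along in-slice chords
perpendicular to the endocardial contour:

* WT(v): distance from v along the outward endocardial normal to the first
  crossing of the epicardial contour.
* transmurality(v): percentage of that same endo->epi chord that passes
  through scar pixels.

Chords are evaluated in-slice (2-D): both quantities are defined by the
short-axis measurement convention, and a 3-D formulation would require a
long-axis definition the planning workflow does not need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import trimesh
from shapely.geometry import Polygon

from cartoplan import _poly

if TYPE_CHECKING:  # pragma: no cover
    from cartoplan.scarseg import ScarSegmentation


@dataclass
class SliceContours:
    """One short-axis slice: z position plus closed endo and epi polylines (mm)."""

    z: float
    endo: np.ndarray
    epi: np.ndarray

    def __post_init__(self) -> None:
        self.endo = _poly.as_open_ring(self.endo)
        self.epi = _poly.as_open_ring(self.epi)


@dataclass
class ContourStack:
    """Ordered per-slice endo/epi contours; slices apex->base with increasing z."""

    slices: list[SliceContours]

    def __post_init__(self) -> None:
        zs = [s.z for s in self.slices]
        if len(zs) >= 2 and not np.all(np.diff(zs) > 0):
            raise ValueError("slice z positions must be strictly increasing (apex->base)")

    def validate(self) -> None:
        """Check closure, simplicity and endo-inside-epi for every slice."""
        for k, s in enumerate(self.slices):
            for name, ring in (("endo", s.endo), ("epi", s.epi)):
                if len(ring) < 8:
                    raise ValueError(f"slice {k}: {name} contour has <8 points")
                # an open arc is not a contour: the implicit closing segment
                # must be a small fraction of the perimeter
                seg = _poly.ring_segment_lengths(ring)
                if seg[-1] > 0.25 * seg.sum():
                    raise ValueError(f"slice {k}: {name} contour is not closed")
                if not _poly.is_simple_ring(ring):
                    raise ValueError(f"slice {k}: {name} contour is self-intersecting")
            if not Polygon(s.epi).contains(Polygon(s.endo)):
                raise ValueError(f"slice {k}: endo contour is not strictly inside epi")

    @property
    def zs(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    def nearest_slice(self, z: float) -> int:
        return int(np.argmin(np.abs(self.zs - z)))

    # -- JSON I/O (per-slice ordered [x, y] mm lists) ------------------

    def to_json(self, path) -> None:
        payload = {
            "slices": [
                {"z": s.z, "endo": s.endo.tolist(), "epi": s.epi.tolist()}
                for s in self.slices
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ContourStack":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(slices=[
            SliceContours(z=float(d["z"]), endo=np.asarray(d["endo"], dtype=float),
                          epi=np.asarray(d["epi"], dtype=float))
            for d in payload["slices"]
        ])


@dataclass
class EndoSurfaceMap:
    """Endocardial tube mesh with per-vertex scalar fields.

    ``vertices`` are ordered slice-major: vertex ``k*points_per_slice + j`` is
    ring point ``j`` of slice ``k``.  Scalars are initialised to NaN by
    :func:`build_endo_mesh` and populated by :func:`compute_surface_maps`.
    """

    vertices: np.ndarray          # (M, 3) mm
    faces: np.ndarray             # (F, 3) vertex index triples
    transmurality: np.ndarray     # (M,) percent
    wall_thickness: np.ndarray    # (M,) mm
    slice_index: np.ndarray       # (M,) int
    angle: np.ndarray             # (M,) degrees CCW from +x about the slice centroid
    points_per_slice: int
    slice_centroids: np.ndarray = field(default=None)  # (n_slices, 2) mm
    slice_zs: np.ndarray = field(default=None)

    @property
    def n_slices(self) -> int:
        return len(self.vertices) // self.points_per_slice

    def ring_vertex_indices(self, k: int) -> np.ndarray:
        n = self.points_per_slice
        return np.arange(k * n, (k + 1) * n)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def save_ply(self, path, scalar_csv=None) -> None:
        """Write geometry as PLY; per-vertex scalars go to a sidecar CSV."""
        self.to_trimesh().export(str(path))
        if scalar_csv is not None:
            import pandas as pd

            pd.DataFrame({
                "vertex": np.arange(len(self.vertices)),
                "slice_index": self.slice_index,
                "angle_deg": self.angle,
                "transmurality_pct": self.transmurality,
                "wall_thickness_mm": self.wall_thickness,
            }).to_csv(scalar_csv, index=False)


def build_endo_mesh(stack: ContourStack, points_per_slice: int = 120) -> EndoSurfaceMap:
    """Resample endocardial contours and stitch adjacent rings into a tube.

    Each endo polyline is resampled to ``points_per_slice`` equal-arc-length
    vertices starting at angle 0 (ray from the contour centroid along +x), so
    ring vertices correspond by index across slices; adjacent rings are then
    triangulated index-wise.  Scalar fields start as NaN.
    """
    if len(stack.slices) < 2:
        raise ValueError("need at least 2 slices to build a surface")
    stack.validate()

    n = points_per_slice
    rings, centroids, angles = [], [], []
    for k, s in enumerate(stack.slices):
        ring = _poly.resample_ring(s.endo, n)
        c = _poly.as_open_ring(s.endo).mean(axis=0)
        rel = ring - c
        ang = np.degrees(np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi))
        rings.append(np.column_stack([ring, np.full(n, s.z)]))
        centroids.append(c)
        angles.append(ang)

    vertices = np.vstack(rings)
    faces = []
    for k in range(len(stack.slices) - 1):
        a = k * n
        b = (k + 1) * n
        for j in range(n):
            jn = (j + 1) % n
            faces.append([a + j, a + jn, b + j])
            faces.append([a + jn, b + jn, b + j])
    m = len(vertices)
    return EndoSurfaceMap(
        vertices=vertices,
        faces=np.asarray(faces, dtype=int),
        transmurality=np.full(m, np.nan),
        wall_thickness=np.full(m, np.nan),
        slice_index=np.repeat(np.arange(len(stack.slices)), n),
        angle=np.concatenate(angles),
        points_per_slice=n,
        slice_centroids=np.asarray(centroids),
        slice_zs=stack.zs,
    )


def _ring_chord(endo_ring: np.ndarray, i: int, epi_ring: np.ndarray,
                centroid: np.ndarray):
    """Endo->epi chord at ring vertex ``i``: returns (direction, length).

    The chord direction is the outward in-slice normal of the endocardial
    contour, estimated by central difference of the neighbouring resampled
    vertices and sign-oriented away from the contour centroid.  If that ray
    misses the epicardial polyline the ray from the centroid through the
    vertex is used instead.
    """
    n = len(endo_ring)
    v = endo_ring[i]
    tangent = endo_ring[(i + 1) % n] - endo_ring[(i - 1) % n]
    normal = np.array([tangent[1], -tangent[0]])
    norm = np.linalg.norm(normal)
    if norm > 0:
        normal = normal / norm
        if np.dot(normal, v - centroid) < 0:
            normal = -normal
        s = _poly.ray_ring_intersection(v, normal, epi_ring)
        if s is not None:
            return normal, s
    # fallback: centroid ray
    direction = v - centroid
    dn = np.linalg.norm(direction)
    if dn == 0:
        return None, None
    direction = direction / dn
    s = _poly.ray_ring_intersection(v, direction, epi_ring)
    if s is None:
        return None, None
    return direction, s


def _slice_chords(s: SliceContours, endo_ring: np.ndarray, slice_name: str):
    """Chord direction and length for every vertex of one resampled endo ring."""
    centroid = endo_ring.mean(axis=0)
    dirs = np.empty_like(endo_ring)
    lengths = np.empty(len(endo_ring))
    for i in range(len(endo_ring)):
        d, length = _ring_chord(endo_ring, i, s.epi, centroid)
        if d is None:
            rel = endo_ring[i] - centroid
            ang = np.degrees(np.arctan2(rel[1], rel[0]))
            raise ValueError(
                f"{slice_name}: chord at angle {ang:.1f} deg misses the epicardial "
                "contour by both the normal-ray and centroid-ray strategies")
        dirs[i] = d
        lengths[i] = length
    return dirs, lengths


def wall_thickness(stack: ContourStack, vertex: np.ndarray, slice_index: int | None = None,
                   points_per_slice: int = 720) -> float:
    """Wall thickness (mm) at a point on an endocardial contour.

    ``vertex`` may be ``[x, y]`` with an explicit ``slice_index`` or
    ``[x, y, z]`` (nearest slice by z).  The point is snapped to the nearest
    vertex of a dense equal-arc-length resampling of the endo contour.
    """
    vertex = np.asarray(vertex, dtype=float)
    if slice_index is None:
        if vertex.shape[0] != 3:
            raise ValueError("need slice_index or a 3-D vertex")
        slice_index = stack.nearest_slice(vertex[2])
    s = stack.slices[slice_index]
    ring = _poly.resample_ring(s.endo, points_per_slice)
    i = int(np.argmin(np.linalg.norm(ring - vertex[:2], axis=1)))
    d, length = _ring_chord(ring, i, s.epi, ring.mean(axis=0))
    if d is None:
        raise ValueError(f"slice {slice_index}: chord misses the epicardial contour")
    return float(length)


def _chord_scar_fraction(origin: np.ndarray, direction: np.ndarray, length: float,
                         mask: np.ndarray, grid_origin: np.ndarray, spacing: float,
                         step: float) -> float:
    """Fraction of the chord passing through True pixels of a slice mask."""
    n_samples = max(int(np.ceil(length / step)), 2)
    t = (np.arange(n_samples) + 0.5) / n_samples * length
    pts = origin[np.newaxis, :] + t[:, np.newaxis] * direction[np.newaxis, :]
    cols = np.round((pts[:, 0] - grid_origin[0]) / spacing).astype(int)
    rows = np.round((pts[:, 1] - grid_origin[1]) / spacing).astype(int)
    inside = (cols >= 0) & (cols < mask.shape[1]) & (rows >= 0) & (rows < mask.shape[0])
    hit = np.zeros(n_samples, dtype=bool)
    hit[inside] = mask[rows[inside], cols[inside]]
    return float(hit.mean())


def transmurality(stack: ContourStack, scar: "ScarSegmentation", vertex: np.ndarray,
                  slice_index: int | None = None, points_per_slice: int = 720) -> float:
    """Infarct transmurality (%) at a point on an endocardial contour.

    Along the same endo->epi chord used for wall thickness, transmurality is
    100 x (chord length inside scar pixels) / (chord length), sampled at a
    quarter of the pixel spacing.
    """
    vertex = np.asarray(vertex, dtype=float)
    if slice_index is None:
        if vertex.shape[0] != 3:
            raise ValueError("need slice_index or a 3-D vertex")
        slice_index = stack.nearest_slice(vertex[2])
    s = stack.slices[slice_index]
    ring = _poly.resample_ring(s.endo, points_per_slice)
    i = int(np.argmin(np.linalg.norm(ring - vertex[:2], axis=1)))
    d, length = _ring_chord(ring, i, s.epi, ring.mean(axis=0))
    if d is None:
        raise ValueError(f"slice {slice_index}: chord misses the epicardial contour")
    frac = _chord_scar_fraction(ring[i], d, length, scar.masks[slice_index],
                                scar.origin, scar.spacing, 0.25 * scar.spacing)
    return 100.0 * frac


def compute_surface_maps(stack: ContourStack, scar: "ScarSegmentation",
                         points_per_slice: int = 120) -> EndoSurfaceMap:
    """Build the endocardial mesh and populate WT and transmurality per vertex."""
    emap = build_endo_mesh(stack, points_per_slice)
    n = points_per_slice
    step = 0.25 * scar.spacing
    for k, s in enumerate(stack.slices):
        ring = emap.vertices[emap.ring_vertex_indices(k)][:, :2]
        dirs, lengths = _slice_chords(s, ring, f"slice {k}")
        frac = np.array([
            _chord_scar_fraction(ring[i], dirs[i], lengths[i], scar.masks[k],
                                 scar.origin, scar.spacing, step)
            for i in range(n)
        ])
        idx = emap.ring_vertex_indices(k)
        emap.wall_thickness[idx] = lengths
        emap.transmurality[idx] = 100.0 * frac
    if np.any(np.isnan(emap.transmurality)) or np.any(np.isnan(emap.wall_thickness)):
        raise AssertionError("scalar projection left NaN vertices")
    return emap
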