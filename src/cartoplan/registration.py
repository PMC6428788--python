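"""Two-stage rigid registration of planning geometry to an interventional cloud.

Stage 1 (:func:`coarse_align`) emulates the "align the volumes first" step of
a fusion workstation: centroids are matched and the principal axes of the two
clouds are aligned, with the four proper axis-sign combinations
disambiguated by symmetric nearest-neighbour RMS.  Stage 2
(:func:`icp_refine`) is trimmed point-to-point ICP with a closed-form SVD
rigid fit per iteration; trimming (default keep the best 80% of
correspondences) makes the refinement robust to partial coverage of the
interventional surface.  Registration is rigid only — both modalities are
metric (mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """x -> R x + t with R a proper rotation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(cls, axis: np.ndarray, angle_deg: float,
                        translation: np.ndarray = (0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = np.radians(angle_deg)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
        return cls(rotation=rot, translation=np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(rotation=self.rotation @ other.rotation,
                              translation=self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(rotation=np.asarray(d["rotation"]), translation=np.asarray(d["translation"]))


def _symmetric_nn_rms(a: np.ndarray, b: np.ndarray) -> float:
    da = cKDTree(b).query(a)[0]
    db = cKDTree(a).query(b)[0]
    return float(np.sqrt(0.5 * (np.mean(da ** 2) + np.mean(db ** 2))))


def coarse_align(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Centroid + principal-axes initialisation.

    The rotation maps the source principal axes onto the target's; among the
    four proper sign assignments of the axes, the one with the smallest
    symmetric nearest-neighbour RMS wins.  A degenerate (rank < 3) point
    distribution falls back to a centroid-only translation with a warning.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if len(src) < 10 or len(tgt) < 10:
        raise ValueError("coarse_align needs at least 10 points per cloud")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    cs = np.cov((src - mu_s).T)
    ct = np.cov((tgt - mu_t).T)
    ws, vs = np.linalg.eigh(cs)
    wt, vt = np.linalg.eigh(ct)
    scale = max(np.max(ws), np.max(wt), 1.0)
    if np.min(ws) < 1e-12 * scale or np.min(wt) < 1e-12 * scale:
        logger.warning("degenerate point distribution (rank < 3); centroid-only alignment")
        return RigidTransform(translation=mu_t - mu_s)
    # eigh returns ascending eigenvalues; order axes major->minor
    vs, vt = vs[:, ::-1], vt[:, ::-1]
    best: RigidTransform | None = None
    best_rms = np.inf
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            flip = np.diag([s1, s2, s1 * s2])  # keeps det(vs @ flip) sign
            vsf = vs @ flip
            rot = vt @ vsf.T
            if np.linalg.det(rot) < 0:  # enforce proper rotation
                rot = (vt @ np.diag([1.0, 1.0, -1.0])) @ vsf.T
            tf = RigidTransform(rotation=rot, translation=mu_t - rot @ mu_s)
            rms = _symmetric_nn_rms(tf.apply(src), tgt)
            if rms < best_rms:
                best, best_rms = tf, rms
    return best


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    n_iter: int
    rms_history: list[float]


def _best_fit_rigid(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit (SVD of the cross-covariance)."""
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    h = (src - mu_s).T @ (tgt - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=mu_t - rot @ mu_s)


def icp_refine(source: np.ndarray, target: np.ndarray,
               init: RigidTransform | None = None,
               max_iter: int = 100, tol: float = 1e-4,
               trim_fraction: float = 0.2) -> ICPResult:
    """Trimmed point-to-point ICP.

    Per iteration: nearest-neighbour correspondences from the moved source to
    the target, keep the best ``1 - trim_fraction`` matches by distance, fit
    the rigid motion in closed form, and stop when the trimmed RMS improves
    by less than ``tol`` mm (or after ``max_iter`` iterations).  Returns the
    total transform (composed with ``init``) and the final trimmed RMS.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(tgt))):
        raise ValueError("point clouds contain non-finite coordinates")
    if not (0.0 <= trim_fraction < 1.0):
        raise ValueError("trim_fraction must be in [0, 1)")
    tf = init if init is not None else RigidTransform.identity()
    tree = cKDTree(tgt)
    n_keep = max(int(np.ceil((1.0 - trim_fraction) * len(src))), 3)
    history: list[float] = []
    prev = np.inf
    moved = tf.apply(src)
    for it in range(max_iter):
        dist, nn = tree.query(moved)
        keep = np.argsort(dist)[:n_keep]
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(rms)
        if prev - rms < tol:
            break
        prev = rms
        step = _best_fit_rigid(moved[keep], tgt[nn[keep]])
        tf = step.compose(tf)
        moved = tf.apply(src)
    dist, _ = tree.query(moved)
    keep = np.argsort(dist)[:n_keep]
    final_rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
    history.append(final_rms)
    return ICPResult(transform=tf, rms=final_rms, n_iter=len(history) - 1,
                     rms_history=history)


def register_two_stage(source: np.ndarray, target: np.ndarray,
                       max_iter: int = 100, tol: float = 1e-4,
                       trim_fraction: float = 0.2) -> ICPResult:
    """Coarse principal-axes alignment followed by trimmed ICP refinement."""
    init = coarse_align(source, target)
    return icp_refine(source, target, init=init, max_iter=max_iter, tol=tol,
                      trim_fraction=trim_fraction)


def apply_transform(obj, tf: RigidTransform):
    """Apply a rigid transform to a point array, TargetPlan or EndoSurfaceMap.

    Coordinates are mapped x -> R x + t; scalars and labels are untouched.
    Returns a new object of the same type.
    """
    from cartoplan.cardiac_maps import EndoSurfaceMap
    from cartoplan.planner import Target, TargetPlan

    if isinstance(obj, np.ndarray):
        return tf.apply(obj)
    if isinstance(obj, EndoSurfaceMap):
        return EndoSurfaceMap(
            vertices=tf.apply(obj.vertices),
            faces=obj.faces.copy(),
            transmurality=obj.transmurality.copy(),
            wall_thickness=obj.wall_thickness.copy(),
            slice_index=obj.slice_index.copy(),
            angle=obj.angle.copy(),
            points_per_slice=obj.points_per_slice,
            slice_centroids=None if obj.slice_centroids is None else obj.slice_centroids.copy(),
            slice_zs=None if obj.slice_zs is None else obj.slice_zs.copy(),
        )
    if isinstance(obj, TargetPlan):
        targets = [
            Target(position=tf.apply(t.position), slice_index=t.slice_index,
                   angle=t.angle, sector=t.sector, needle_depth=t.needle_depth,
                   vertex_index=t.vertex_index)
            for t in obj.targets
        ]
        return TargetPlan(targets=targets, ibz_vertices=obj.ibz_vertices.copy(),
                          danger_vertices=obj.danger_vertices.copy())
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")
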