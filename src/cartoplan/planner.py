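"""IBZ delineation and injection-target assignment on the endocardial map.

The infarct border zone (IBZ) is the set of map vertices with transmurality
between ``transmurality_low`` and ``transmurality_high`` (default 1-20%,
inclusive at both ends) and wall thickness above ``wt_min`` (default 5 mm,
strict).  Danger zones — unsafe for injection — are vertices with
transmurality above the high bound (dense scar) or wall thickness below
``wt_min`` (perforation risk).  A vertex at exactly WT = 5 mm is neither IBZ
("> 5 mm") nor danger ("< 5 mm"): it is neutral.

Targets are distributed "equally over the septal and anterior side" by greedy
farthest-point sampling per sector under the 3-D Euclidean metric, seeded at
the IBZ vertex closest to the sector's angular centre: a deterministic
realisation of spatial spread.  The needle depth recommendation is half the
local wall thickness by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from cartoplan.cardiac_maps import EndoSurfaceMap

SECTORS = ("septal", "anterior")


@dataclass
class PlannerConfig:
    """Target-zone bounds and target-count configuration.

    ``septal_direction`` is the in-slice unit vector toward the septum; the
    septal sector is the half of the circumference within 90 degrees of it.
    The phantom supplies this direction; for real data the operator must.
    """

    transmurality_low: float = 1.0
    transmurality_high: float = 20.0
    wt_min: float = 5.0
    n_targets: int = 16
    sector_split: dict = field(default_factory=lambda: {"septal": 8, "anterior": 8})
    needle_depth_fraction: float = 0.5
    septal_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        if not (0.0 <= self.transmurality_low < self.transmurality_high <= 100.0):
            raise ValueError("need 0 <= transmurality_low < transmurality_high <= 100")
        if self.wt_min <= 0:
            raise ValueError("wt_min must be positive")
        if sum(self.sector_split.values()) != self.n_targets:
            raise ValueError("sector_split counts must sum to n_targets")
        if not (0.0 < self.needle_depth_fraction <= 1.0):
            raise ValueError("needle_depth_fraction must be in (0, 1]")
        d = np.asarray(self.septal_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("septal_direction must be a non-zero 2-vector")
        self.septal_direction = d / n


@dataclass
class Target:
    position: np.ndarray   # 3-D mm
    slice_index: int
    angle: float           # degrees
    sector: str
    needle_depth: float    # mm
    vertex_index: int

    def to_dict(self) -> dict:
        return {
            "position_mm": list(map(float, self.position)),
            "slice_index": int(self.slice_index),
            "angle_deg": float(self.angle),
            "sector": self.sector,
            "needle_depth_mm": float(self.needle_depth),
            "vertex_index": int(self.vertex_index),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Target":
        return cls(position=np.asarray(d["position_mm"], dtype=float),
                   slice_index=d["slice_index"], angle=d["angle_deg"],
                   sector=d["sector"], needle_depth=d["needle_depth_mm"],
                   vertex_index=d["vertex_index"])


@dataclass
class TargetPlan:
    targets: list[Target]
    ibz_vertices: np.ndarray
    danger_vertices: np.ndarray

    def positions(self) -> np.ndarray:
        return np.array([t.position for t in self.targets])

    def to_json(self, path) -> None:
        payload = {
            "targets": [t.to_dict() for t in self.targets],
            "ibz_vertices": self.ibz_vertices.tolist(),
            "danger_vertices": self.danger_vertices.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TargetPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(targets=[Target.from_dict(d) for d in payload["targets"]],
                   ibz_vertices=np.asarray(payload["ibz_vertices"], dtype=int),
                   danger_vertices=np.asarray(payload["danger_vertices"], dtype=int))


def classify_vertices(emap: EndoSurfaceMap,
                      cfg: PlannerConfig) -> tuple[np.ndarray, np.ndarray]:
    """Partition map vertices into IBZ and danger index sets.

    IBZ: low <= T <= high and WT > wt_min.  Danger: T > high or WT < wt_min.
    Everything else is neutral.  The two sets are disjoint by construction.
    """
    t = emap.transmurality
    wt = emap.wall_thickness
    if np.any(np.isnan(t)) or np.any(np.isnan(wt)):
        raise ValueError("map scalars are not populated")
    ibz = (t >= cfg.transmurality_low) & (t <= cfg.transmurality_high) & (wt > cfg.wt_min)
    danger = (t > cfg.transmurality_high) | (wt < cfg.wt_min)
    return np.flatnonzero(ibz), np.flatnonzero(danger)


def vertex_sectors(emap: EndoSurfaceMap, septal_direction: np.ndarray) -> np.ndarray:
    """Label every vertex septal or anterior by its in-slice radial direction.

    Septal = radial direction within +-90 degrees of ``septal_direction``
    (boundary inclusive on the septal side).
    """
    if emap.slice_centroids is None:
        raise ValueError("map lacks slice centroids")
    d = np.asarray(septal_direction, dtype=float)
    d = d / np.linalg.norm(d)
    centroids = emap.slice_centroids[emap.slice_index]
    radial = emap.vertices[:, :2] - centroids
    dot = radial @ d
    return np.where(dot >= 0.0, "septal", "anterior")


def _farthest_point_sample(points: np.ndarray, k: int, seed_idx: int) -> list[int]:
    """Greedy k-dispersion: start at ``seed_idx``, then repeatedly add the
    point farthest (3-D Euclidean) from the chosen set.  Ties break to the
    lowest index, so the result is deterministic."""
    chosen = [seed_idx]
    mind = np.linalg.norm(points - points[seed_idx], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(mind))  # argmax takes the first (lowest-index) maximum
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1))
    return chosen


def assign_targets(emap: EndoSurfaceMap, cfg: PlannerConfig) -> TargetPlan:
    """Assign injection targets in the IBZ, spread per sector.

    Within each sector the seed is the IBZ vertex whose radial direction is
    closest to the sector's angular centre (the septal direction or its
    opposite); the remaining targets follow by farthest-point sampling.
    Raises when a sector holds fewer IBZ vertices than requested.
    """
    ibz_idx, danger_idx = classify_vertices(emap, cfg)
    sectors = vertex_sectors(emap, cfg.septal_direction)
    centroids = emap.slice_centroids[emap.slice_index]
    radial = emap.vertices[:, :2] - centroids
    radial = radial / np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-30)

    deficits = []
    for sector, count in cfg.sector_split.items():
        n_avail = int(np.sum(sectors[ibz_idx] == sector))
        if n_avail < count:
            deficits.append(f"{sector}: requested {count}, available {n_avail}")
    if deficits:
        raise ValueError("insufficient IBZ vertices in sector(s): " + "; ".join(deficits))

    targets: list[Target] = []
    for sector, count in cfg.sector_split.items():
        if count == 0:
            continue
        center_dir = cfg.septal_direction if sector == "septal" else -cfg.septal_direction
        cand = ibz_idx[sectors[ibz_idx] == sector]
        seed_local = int(np.argmax(radial[cand] @ center_dir))
        chosen_local = _farthest_point_sample(emap.vertices[cand], count, seed_local)
        for j in chosen_local:
            v = int(cand[j])
            targets.append(Target(
                position=emap.vertices[v].copy(),
                slice_index=int(emap.slice_index[v]),
                angle=float(emap.angle[v]),
                sector=sector,
                needle_depth=float(cfg.needle_depth_fraction * emap.wall_thickness[v]),
                vertex_index=v,
            ))

    # post-hoc re-check of the IBZ predicate for every emitted target
    for t in targets:
        tv = emap.transmurality[t.vertex_index]
        wv = emap.wall_thickness[t.vertex_index]
        assert cfg.transmurality_low <= tv <= cfg.transmurality_high and wv > cfg.wt_min
    return TargetPlan(targets=targets, ibz_vertices=ibz_idx, danger_vertices=danger_idx)
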