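"""Injection accuracy endpoints: signed along-contour distance to the IBZ, depth.

The primary accuracy measure mimics how injections are scored on short-axis
slices: each retrieved injection is projected onto the endocardial contour of
its slice and the distance to the IBZ band (the 1-20% transmurality arc) is
measured *along the contour*.  The distance is signed — negative when the
injection sits on the infarct side of the band (where transmurality exceeds
the upper bound), positive on the remote side (below the lower bound), and
zero inside the band.  Injection depth is the perpendicular distance from the
endocardial contour into the wall.

Distances are per-slice 2-D measurements; when the injection's slice has no
IBZ arc the nearest slice that does is used, and the out-of-plane offset is
reported separately.  Repeated measurements are summarised per animal and the
study groups are compared on the per-animal means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cartoplan import _poly
from cartoplan.cardiac_maps import ContourStack, EndoSurfaceMap
from cartoplan.planner import PlannerConfig

logger = logging.getLogger(__name__)


@dataclass
class InjectionRecord:
    """A retrieved injection site."""

    animal_id: str
    position: np.ndarray          # [x, y] mm + slice_index, or [x, y, z] mm
    group_label: str = "planned"
    slice_index: int | None = None
    distance_to_ibz: float | None = None
    depth: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


def _resolve_slice(stack: ContourStack, injection: InjectionRecord) -> int:
    if injection.slice_index is not None:
        return int(injection.slice_index)
    if injection.position.shape[0] != 3:
        raise ValueError("injection needs slice_index or a 3-D position")
    return stack.nearest_slice(injection.position[2])


def _ibz_runs(is_ibz: np.ndarray) -> list[np.ndarray]:
    """Maximal circular runs of consecutive True entries, as index arrays."""
    n = len(is_ibz)
    if is_ibz.all():
        return [np.arange(n)]
    idx = np.flatnonzero(is_ibz)
    if len(idx) == 0:
        return []
    # rotate so the scan starts just after a False entry
    start = int(np.flatnonzero(~is_ibz)[0]) + 1
    order = (start + np.arange(n)) % n
    runs, current = [], []
    for i in order:
        if is_ibz[i]:
            current.append(i)
        elif current:
            runs.append(np.asarray(current))
            current = []
    if current:
        runs.append(np.asarray(current))
    return runs


def _ring_arc_positions(ring: np.ndarray) -> tuple[np.ndarray, float]:
    seg = _poly.ring_segment_lengths(ring)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum[:-1], float(cum[-1])


def signed_ibz_distance(stack: ContourStack, emap: EndoSurfaceMap, cfg: PlannerConfig,
                        injection: InjectionRecord,
                        return_details: bool = False):
    """Signed along-contour distance (mm) from an injection to the IBZ band.

    The injection is projected onto the endocardial ring of its slice (the
    nearest slice with a non-empty IBZ arc); the result is the minimal arc
    length to the transmurality band ``[low, high]``, zero inside it,
    negative when the shorter path borders the >high (infarct) side and
    positive when it borders the <low (remote) side.
    """
    k0 = _resolve_slice(stack, injection)
    low, high = cfg.transmurality_low, cfg.transmurality_high

    # nearest slice with an IBZ arc
    candidates = sorted(range(emap.n_slices), key=lambda k: (abs(k - k0), k))
    k_use = None
    for k in candidates:
        t = emap.transmurality[emap.ring_vertex_indices(k)]
        if np.any((t >= low) & (t <= high)):
            k_use = k
            break
    if k_use is None:
        raise ValueError("no slice carries an IBZ arc in the transmurality band")
    out_of_plane = abs(float(emap.slice_zs[k_use] - emap.slice_zs[k0])) \
        if emap.slice_zs is not None else 0.0

    idx = emap.ring_vertex_indices(k_use)
    ring = emap.vertices[idx][:, :2]
    tvals = emap.transmurality[idx]
    is_ibz = (tvals >= low) & (tvals <= high)
    pos, perimeter = _ring_arc_positions(ring)
    _, s_inj, _ = _poly.project_point_to_ring(injection.position[:2], ring)

    def circ_delta(a: float, b: float) -> float:
        """Unsigned circular arc distance from a to b."""
        d = (b - a) % perimeter
        return min(d, perimeter - d)

    best = None  # (distance, boundary_vertex, direction)
    n = len(ring)
    for run in _ibz_runs(is_ibz):
        s_start, s_end = pos[run[0]], pos[run[-1]]
        # inside the run's arc span (run ordered along the ring)
        span = (s_end - s_start) % perimeter
        rel = (s_inj - s_start) % perimeter
        if rel <= span:
            result = (0.0, None, 0)
            if return_details:
                return 0.0, {"slice_used": k_use, "out_of_plane_mm": out_of_plane}
            return 0.0
        for boundary, side in ((run[0], -1), (run[-1], +1)):
            d = circ_delta(s_inj, pos[boundary])
            if best is None or d < best[0]:
                best = (d, boundary, side)
    assert best is not None
    d, boundary, side = best
    # sign from the non-IBZ neighbour adjacent to the reached arc end on the
    # outside of the run: T > high -> infarct side (negative)
    neighbour = (boundary + side) % n
    sign = -1.0 if tvals[neighbour] > high else 1.0
    signed = sign * d
    if return_details:
        return signed, {"slice_used": k_use, "out_of_plane_mm": out_of_plane}
    return signed


def injection_depth(stack: ContourStack, injection: InjectionRecord,
                    dense: int = 2048) -> float:
    """Perpendicular distance (mm) from the endocardial contour to the injection.

    Positive into the wall; an injection on the blood-pool side of the
    contour is reported negative with a warning.
    """
    k = _resolve_slice(stack, injection)
    ring = _poly.resample_ring(stack.slices[k].endo, dense)
    _, _, dist = _poly.project_point_to_ring(injection.position[:2], ring)
    if _poly.point_in_ring(injection.position[:2], ring) and dist > 0:
        logger.warning("injection for animal %s lies on the blood-pool side of the "
                       "endocardium; depth reported negative", injection.animal_id)
        return -dist
    return dist


def evaluate_injections(stack: ContourStack, emap: EndoSurfaceMap, cfg: PlannerConfig,
                        records: list[InjectionRecord]) -> pd.DataFrame:
    """Per-injection table: signed IBZ distance, depth and out-of-plane offset."""
    rows = []
    for rec in records:
        dist, details = signed_ibz_distance(stack, emap, cfg, rec, return_details=True)
        depth = injection_depth(stack, rec)
        rec.distance_to_ibz = dist
        rec.depth = depth
        rows.append({
            "animal_id": rec.animal_id,
            "group": rec.group_label,
            "distance_to_ibz_mm": dist,
            "depth_mm": depth,
            "slice_used": details["slice_used"],
            "out_of_plane_mm": details["out_of_plane_mm"],
        })
    return pd.DataFrame(rows, columns=["animal_id", "group", "distance_to_ibz_mm",
                                       "depth_mm", "slice_used", "out_of_plane_mm"])


def per_animal_summary(records: list[InjectionRecord] | pd.DataFrame) -> pd.DataFrame:
    """One row per animal: mean signed distance, mean depth, number of injections.

    Repeated measurements enter group comparisons through these per-animal
    means, never pooled across animals.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([{
            "animal_id": r.animal_id,
            "group": r.group_label,
            "distance_to_ibz_mm": r.distance_to_ibz,
            "depth_mm": r.depth,
        } for r in records])
    if df.empty:
        return pd.DataFrame(columns=["animal_id", "group", "mean_distance_mm",
                                     "mean_depth_mm", "n_injections"])
    out = (df.groupby(["animal_id", "group"], as_index=False)
             .agg(mean_distance_mm=("distance_to_ibz_mm", "mean"),
                  mean_depth_mm=("depth_mm", "mean"),
                  n_injections=("distance_to_ibz_mm", "size")))
    return out[["animal_id", "group", "mean_distance_mm", "mean_depth_mm", "n_injections"]]
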