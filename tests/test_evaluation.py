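"""Signed along-contour IBZ distance, injection depth, per-animal summaries."""

import numpy as np
import pandas as pd
import pytest

import cartoplan as cp
from cartoplan.cardiac_maps import EndoSurfaceMap
from cartoplan.evaluation import (InjectionRecord, injection_depth, per_animal_summary,
                                  signed_ibz_distance)
from cartoplan.planner import PlannerConfig

from conftest import circle


def ring_map(tvals, radius=20.0, n=None):
    """Two identical rings with a prescribed per-vertex transmurality field."""
    n = n or len(tvals)
    ang = 2 * np.pi * np.arange(n) / n
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
    vertices = np.vstack([np.column_stack([ring, np.zeros(n)]),
                          np.column_stack([ring, np.full(n, 5.0)])])
    return EndoSurfaceMap(
        vertices=vertices, faces=np.zeros((0, 3), int),
        transmurality=np.tile(np.asarray(tvals, float), 2),
        wall_thickness=np.full(2 * n, 10.0),
        slice_index=np.repeat([0, 1], n),
        angle=np.tile(np.degrees(ang), 2),
        points_per_slice=n,
        slice_centroids=np.zeros((2, 2)),
        slice_zs=np.array([0.0, 5.0]))


def ring_stack(radius=20.0):
    return cp.ContourStack(slices=[
        cp.SliceContours(z=0.0, endo=circle(radius, n=360), epi=circle(radius + 10, n=360)),
        cp.SliceContours(z=5.0, endo=circle(radius, n=360), epi=circle(radius + 10, n=360))])


def banded_tvals(n=360):
    """IBZ arc on [0, 30] deg, dense scar below 0 deg, remote elsewhere."""
    ang = 360.0 * np.arange(n) / n
    t = np.zeros(n)
    t[(ang >= 0) & (ang <= 30)] = 10.0
    t[(ang > 330) & (ang < 360)] = 50.0
    return t


def inj(theta_deg, radius=20.0, animal="a1", depth_offset=0.0):
    a = np.radians(theta_deg)
    r = radius + depth_offset
    return InjectionRecord(animal_id=animal, position=np.array(
        [r * np.cos(a), r * np.sin(a)]), slice_index=0)


class TestSignedIBZDistance:
    def setup_method(self):
        self.stack = ring_stack()
        self.emap = ring_map(banded_tvals())
        self.cfg = PlannerConfig()

    def test_inside_arc_zero(self):
        assert signed_ibz_distance(self.stack, self.emap, self.cfg, inj(15.0)) == 0.0

    def test_remote_side_positive_arc_length(self):
        # injection 30 deg beyond the arc end on the remote side
        d = signed_ibz_distance(self.stack, self.emap, self.cfg, inj(60.0))
        assert d == pytest.approx(20.0 * np.radians(30.0), abs=0.02)
        assert d > 0

    def test_infarct_side_negative(self):
        d = signed_ibz_distance(self.stack, self.emap, self.cfg, inj(-15.0))
        assert d == pytest.approx(-20.0 * np.radians(15.0), abs=0.02)

    def test_brute_force_agreement_100_random_toys(self):
        """Signed distance matches exhaustive arc-length search within 0.05 mm."""
        rng = np.random.default_rng(123)
        cfg = PlannerConfig()
        for _ in range(100):
            n = 360
            radius = rng.uniform(15.0, 30.0)
            arc_start = rng.uniform(0.0, 360.0)
            arc_len = rng.uniform(20.0, 120.0)
            ang = 360.0 * np.arange(n) / n
            rel = (ang - arc_start) % 360.0
            t = np.zeros(n)
            t[rel <= arc_len] = rng.uniform(2.0, 19.0)
            infarct = (rel > 360.0 - 60.0)  # 60 deg dense scar hugging arc start
            t[infarct] = rng.uniform(25.0, 90.0)
            emap = ring_map(t, radius=radius)
            stack = ring_stack(radius=radius)
            theta_inj = rng.uniform(0.0, 360.0)
            record = inj(theta_inj, radius=radius)
            got = signed_ibz_distance(stack, emap, cfg, record)

            # exhaustive oracle: walk a dense resampling of the polygonal ring
            ring = emap.vertices[:n, :2]
            seg = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            perimeter = cum[-1]
            is_ibz = (t >= 1.0) & (t <= 20.0)
            # dense arc positions; a dense point between vertices j, j+1 is
            # in the band iff both vertices are
            m = 72000
            s_dense = np.linspace(0.0, perimeter, m, endpoint=False)
            j_seg = np.clip(np.searchsorted(cum, s_dense, side="right") - 1, 0, n - 1)
            in_band = is_ibz[j_seg] & is_ibz[(j_seg + 1) % n]
            in_band[np.isin(j_seg, np.flatnonzero(is_ibz)) &
                    (s_dense - cum[j_seg] < 1e-9)] = True
            # injection arc position: brute-force closest dense point
            closed = np.vstack([ring, ring[:1]])
            xs = np.interp(s_dense, cum, closed[:, 0])
            ys = np.interp(s_dense, cum, closed[:, 1])
            p = record.position[:2]
            s_inj = s_dense[int(np.argmin((xs - p[0]) ** 2 + (ys - p[1]) ** 2))]
            dd = np.abs(s_dense[in_band] - s_inj)
            dist = float(np.min(np.minimum(dd, perimeter - dd)))
            assert abs(abs(got) - dist) <= 0.05

    def test_no_ibz_anywhere_raises(self):
        emap = ring_map(np.zeros(360))
        with pytest.raises(ValueError, match="IBZ"):
            signed_ibz_distance(self.stack, emap, self.cfg, inj(10.0))

    def test_nearest_slice_with_ibz_used(self):
        t = banded_tvals()
        emap = ring_map(t)
        emap.transmurality[:360] = 0.0  # slice 0 has no band; slice 1 does
        d, details = signed_ibz_distance(self.stack, emap, self.cfg, inj(15.0),
                                         return_details=True)
        assert details["slice_used"] == 1
        assert details["out_of_plane_mm"] == pytest.approx(5.0)
        assert d == 0.0


class TestInjectionDepth:
    def test_outward_offset_is_depth(self):
        stack = ring_stack()
        assert injection_depth(stack, inj(40.0, depth_offset=3.0)) == \
            pytest.approx(3.0, abs=0.01)

    def test_on_contour_zero(self):
        stack = ring_stack()
        assert injection_depth(stack, inj(40.0)) == pytest.approx(0.0, abs=0.01)

    def test_blood_pool_side_negative(self):
        stack = ring_stack()
        d = injection_depth(stack, inj(40.0, depth_offset=-2.0))
        assert d == pytest.approx(-2.0, abs=0.01)


class TestPerAnimalSummary:
    def test_single_animal_mean(self):
        recs = [InjectionRecord("a1", np.zeros(2), distance_to_ibz=d, depth=1.0,
                                slice_index=0) for d in (1.0, 2.0, 3.0)]
        out = per_animal_summary(recs)
        assert len(out) == 1
        assert out["mean_distance_mm"].iloc[0] == pytest.approx(2.0)

    def test_grand_mean_is_mean_of_animal_means(self):
        recs = ([InjectionRecord("a1", np.zeros(2), distance_to_ibz=d, depth=0.0,
                                 slice_index=0) for d in (0.0, 0.0, 6.0)]
                + [InjectionRecord("a2", np.zeros(2), distance_to_ibz=4.0, depth=0.0,
                                   slice_index=0)])
        out = per_animal_summary(recs)
        assert len(out) == 2
        grand = out["mean_distance_mm"].mean()
        assert grand == pytest.approx((2.0 + 4.0) / 2.0)  # not the pooled mean 2.5

    def test_empty_input_empty_table(self):
        out = per_animal_summary([])
        assert out.empty


class TestEndToEndPhantomRecovery:
    def test_injections_on_planned_targets_recover_small_distance(self, default_plan):
        """Synthetic injections placed on the plan land in the band (|mean| < 1 mm)."""
        plan, emap, truth = (default_plan["plan"], default_plan["emap"],
                             default_plan["truth"])
        stack = truth.contours
        cfg = default_plan["cfg"]
        records = []
        for i, t in enumerate(plan.targets):
            records.append(InjectionRecord(animal_id=f"p{i % 5}", position=t.position,
                                           slice_index=t.slice_index))
        dists = [signed_ibz_distance(stack, emap, cfg, r) for r in records]
        per_animal = pd.DataFrame({"animal": [r.animal_id for r in records],
                                   "d": np.abs(dists)})
        means = per_animal.groupby("animal")["d"].mean()
        assert means.max() < 1.0

    def test_depth_of_offset_injections_matches_needle_depth(self, default_plan):
        plan, truth = default_plan["plan"], default_plan["truth"]
        stack = truth.contours
        for t in plan.targets[:4]:
            centroid = stack.slices[t.slice_index].endo.mean(axis=0)
            direction = t.position[:2] - centroid
            direction /= np.linalg.norm(direction)
            pos = t.position[:2] + t.needle_depth * direction
            rec = InjectionRecord("a", pos, slice_index=t.slice_index)
            assert injection_depth(stack, rec) == pytest.approx(t.needle_depth, abs=0.1)
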