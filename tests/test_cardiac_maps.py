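"""Surface mesh construction and per-vertex wall thickness / transmurality."""

import numpy as np
import pytest

import cartoplan as cp
from cartoplan import _poly
from cartoplan.cardiac_maps import (build_endo_mesh, compute_surface_maps, transmurality,
                                    wall_thickness)
from cartoplan.scarseg import ScarSegmentation

from conftest import circle


class TestBuildEndoMesh:
    def test_two_rings_vertex_and_face_counts(self, concentric_stack):
        emap = build_endo_mesh(concentric_stack, points_per_slice=4)
        assert emap.vertices.shape == (8, 3)
        assert emap.faces.shape == (8, 3)
        assert np.all(np.isnan(emap.transmurality))

    def test_resampled_ring_arc_length_matches_circumference(self, concentric_stack):
        emap = build_endo_mesh(concentric_stack, points_per_slice=360)
        ring = emap.vertices[emap.ring_vertex_indices(0)][:, :2]
        perimeter = _poly.ring_perimeter(ring)
        assert perimeter == pytest.approx(2 * np.pi * 20.0, abs=0.01)

    def test_rings_start_at_angle_zero(self, concentric_stack):
        emap = build_endo_mesh(concentric_stack, points_per_slice=8)
        first = emap.vertices[emap.ring_vertex_indices(0)][0]
        # start point lies at the +x crossing, up to the dense-resampling step
        assert first[1] == pytest.approx(0.0, abs=0.05)
        assert first[0] > 0

    def test_open_arc_contour_rejected(self):
        arc = circle(20.0, n=180)[:45]  # quarter circle, not a closed contour
        stack = cp.ContourStack(slices=[
            cp.SliceContours(z=0.0, endo=arc, epi=circle(30.0)),
            cp.SliceContours(z=5.0, endo=circle(20.0), epi=circle(30.0))])
        with pytest.raises(ValueError, match="slice 0.*not closed"):
            build_endo_mesh(stack)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10],
                           [-2, 8], [-3, 5], [-3, 4], [-2, 2]], dtype=float)
        stack = cp.ContourStack(slices=[
            cp.SliceContours(z=0.0, endo=circle(20.0), epi=circle(30.0)),
            cp.SliceContours(z=5.0, endo=bowtie, epi=circle(30.0))])
        with pytest.raises(ValueError, match="slice 1.*self-intersecting"):
            build_endo_mesh(stack)

    def test_single_slice_rejected(self):
        stack = cp.ContourStack(slices=[
            cp.SliceContours(z=0.0, endo=circle(20.0), epi=circle(30.0))])
        with pytest.raises(ValueError, match="2 slices"):
            build_endo_mesh(stack)


class TestWallThickness:
    def test_concentric_circles_exact(self, concentric_stack):
        # contours are 360-gons: chords undercut the circle by ~2e-3 mm
        emap = compute_surface_maps(concentric_stack, _empty_scar(concentric_stack))
        assert emap.wall_thickness == pytest.approx(10.0, abs=5e-3)

    def test_single_vertex_api(self, concentric_stack):
        wt = wall_thickness(concentric_stack, np.array([20.0, 0.0, 0.0]))
        assert wt == pytest.approx(10.0, abs=5e-3)

    def test_ellipse_in_circle_matches_brute_force(self):
        """Normal-ray crossing agrees with dense sampling of the epi polyline."""
        ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ellipse = np.column_stack([14.0 * np.cos(ang), 9.0 * np.sin(ang)])
        stack = cp.ContourStack(slices=[
            cp.SliceContours(z=float(z), endo=ellipse, epi=circle(25.0, n=720))
            for z in (0.0, 5.0)])
        emap = build_endo_mesh(stack, points_per_slice=36)
        ring = emap.vertices[emap.ring_vertex_indices(0)][:, :2]
        centroid = ring.mean(axis=0)
        epi_dense = _poly.resample_ring(circle(25.0, n=720), 200000)
        for i in range(0, 36, 5):
            n_vec = _normal_at(ring, i, centroid)
            wt = cp.cardiac_maps._ring_chord(ring, i, stack.slices[0].epi, centroid)[1]
            # brute force: walk the dense epi polyline, find min positive ray hit
            rel = epi_dense - ring[i]
            t = rel @ n_vec
            perp = rel - np.outer(t, n_vec)
            hits = (t > 0) & (np.linalg.norm(perp, axis=1) < 0.01)
            assert hits.any()
            assert wt == pytest.approx(t[hits].min(), abs=0.02)

    def test_phantom_wall_thickness_recovered(self, default_phantom):
        emap = default_phantom["emap"]
        assert emap.wall_thickness == pytest.approx(10.0, abs=0.1)


def _normal_at(ring, i, centroid):
    n = len(ring)
    tangent = ring[(i + 1) % n] - ring[(i - 1) % n]
    normal = np.array([tangent[1], -tangent[0]])
    normal /= np.linalg.norm(normal)
    if np.dot(normal, ring[i] - centroid) < 0:
        normal = -normal
    return normal


def _empty_scar(stack, shape=(80, 80), origin=(-32.0, -32.0), spacing=0.8):
    return ScarSegmentation(masks=[np.zeros(shape, bool) for _ in stack.slices],
                            thresholds=[np.nan] * len(stack.slices),
                            origin=np.asarray(origin), spacing=spacing, zs=stack.zs)


class TestTransmurality:
    def test_no_scar_zero_everywhere(self, concentric_stack):
        emap = compute_surface_maps(concentric_stack, _empty_scar(concentric_stack))
        assert np.all(emap.transmurality == 0.0)

    def test_full_scar_hundred(self, concentric_stack):
        # scar mask covering the whole grid -> every chord fully inside scar
        scar = ScarSegmentation(masks=[np.ones((200, 200), bool)] * 2,
                                thresholds=[np.nan] * 2,
                                origin=np.array([-40.0, -40.0]), spacing=0.4,
                                zs=concentric_stack.zs)
        emap = compute_surface_maps(concentric_stack, scar)
        assert np.all(emap.transmurality == 100.0)

    def test_wedge30_phantom_recovery(self, wedge30_phantom):
        """Vertices inside a constant-30% wedge read 30 +- 2 pp, outside 0."""
        spec, volume, truth = wedge30_phantom
        emap = compute_surface_maps(truth.contours, truth.scar_segmentation())
        # wedge interior: one full angular step inside [60, 120)
        inside = (emap.angle > 63.0) & (emap.angle < 117.0)
        outside = (emap.angle < 57.0) | (emap.angle > 123.0)
        assert emap.transmurality[inside] == pytest.approx(30.0, abs=2.0)
        assert np.all(emap.transmurality[outside] == 0.0)

    def test_single_vertex_api_matches_map(self, wedge30_phantom):
        spec, volume, truth = wedge30_phantom
        scar = truth.scar_segmentation()
        v = truth.contours.slices[0].endo[90]  # angle 90 deg, wedge core
        t = transmurality(truth.contours, scar, v, slice_index=0)
        assert t == pytest.approx(30.0, abs=2.0)

    def test_rigid_motion_invariance(self, wedge30_phantom):
        """In-plane rigid motion of contours + scar grid leaves maps unchanged."""
        spec, volume, truth = wedge30_phantom
        emap0 = compute_surface_maps(truth.contours, truth.scar_segmentation(),
                                     points_per_slice=60)
        # translate everything by the same in-plane offset
        shift = np.array([7.0, -4.0])
        moved = cp.ContourStack(slices=[
            cp.SliceContours(z=s.z, endo=s.endo + shift, epi=s.epi + shift)
            for s in truth.contours.slices])
        scar = truth.scar_segmentation()
        scar_moved = ScarSegmentation(masks=scar.masks, thresholds=scar.thresholds,
                                      origin=scar.origin + shift, spacing=scar.spacing,
                                      zs=scar.zs)
        emap1 = compute_surface_maps(moved, scar_moved, points_per_slice=60)
        assert np.allclose(emap1.wall_thickness, emap0.wall_thickness, atol=1e-6)
        assert np.allclose(emap1.transmurality, emap0.transmurality, atol=1e-6)

    def test_scalars_total_no_nan(self, default_phantom):
        emap = default_phantom["emap"]
        assert not np.any(np.isnan(emap.transmurality))
        assert not np.any(np.isnan(emap.wall_thickness))
        assert np.all((emap.transmurality >= 0) & (emap.transmurality <= 100))
        assert np.all(emap.wall_thickness > 0)
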