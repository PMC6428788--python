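"""Shared fixtures: phantoms at the default study conditions and toy geometries."""

import numpy as np
import pytest

import cartoplan as cp
from cartoplan.phantom import constant_profile


@pytest.fixture(scope="session")
def default_phantom():
    """Default LV phantom (seed 1) with FWHM segmentation and surface map."""
    spec = cp.PhantomSpec(seed=1)
    volume, truth = cp.generate_phantom(spec)
    scar = cp.segment_volume(list(volume.data), truth.myocardial_masks(),
                             spec.pixel_spacing, origin=truth.grid_origin,
                             zs=truth.contours.zs)
    emap = cp.compute_surface_maps(truth.contours, scar)
    return {"spec": spec, "volume": volume, "truth": truth, "scar": scar, "emap": emap}


@pytest.fixture(scope="session")
def default_plan(default_phantom):
    cfg = cp.PlannerConfig(septal_direction=default_phantom["truth"].septal_direction)
    plan = cp.assign_targets(default_phantom["emap"], cfg)
    return {"cfg": cfg, "plan": plan, **default_phantom}


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free phantom for exact-recovery checks."""
    spec = cp.PhantomSpec(seed=1, noise_sd=0.0)
    volume, truth = cp.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def wedge30_phantom():
    """Concentric phantom with a constant 30% transmurality wedge on a fine grid."""
    spec = cp.PhantomSpec(
        seed=1, noise_sd=0.0, center_drift=(0.0, 0.0), apex_taper=0.0,
        n_slices=4, transmurality_profile=constant_profile(0.3), pixel_spacing=0.2)
    volume, truth = cp.generate_phantom(spec)
    return spec, volume, truth


def circle(radius, n=360, center=(0.0, 0.0), z=None):
    """Closed circular contour helper used by toy geometries."""
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(ang),
                           center[1] + radius * np.sin(ang)])
    if z is None:
        return pts
    return np.column_stack([pts, np.full(n, z)])


@pytest.fixture
def concentric_stack():
    """Two-slice stack of concentric circles: r_endo 20, r_epi 30."""
    slices = [cp.SliceContours(z=float(k * 5), endo=circle(20.0), epi=circle(30.0))
              for k in range(2)]
    return cp.ContourStack(slices=slices)
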