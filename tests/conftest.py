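"""Shared fixtures: phantoms and analytic meshes are generated at test time."""

import numpy as np
import pytest

import vesselquant as vq
from vesselquant.surfaces import ContourSet, SliceContour


def circle_contours(radius, center=(20.0, 20.0), n_slices=60, n_pts=96, name="surface"):
    """Analytic circular contour stack (dz = 1 μm slices)."""
    ang = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    cy, cx = center
    poly = np.column_stack([cy + radius * np.sin(ang), cx + radius * np.cos(ang)])
    return ContourSet(name, [SliceContour(z, poly.copy()) for z in range(n_slices)])


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Lofted circular cylinder r=10 μm, L=60 μm, M=64 (caps included).

    Rings sit at slice centers (z = 0.5 .. 60.5 μm), so 61 slices span
    exactly 60 μm of vessel length.
    """
    return vq.loft_surface(circle_contours(10.0, n_slices=61), (1.0, 0.3, 0.3), 64)


@pytest.fixture(scope="session")
def wt_phantom():
    """One wt_d16 phantom with ground truth (deterministic seed)."""
    spec = vq.phantom_preset("wt_d16", seed=11)
    return vq.generate_phantom(spec)


@pytest.fixture(scope="session")
def wt_report(wt_phantom):
    """Full pipeline report for the shared wt_d16 phantom."""
    stack, _ = wt_phantom
    return vq.analyze_vessel(stack, vessel_id="wt11", group="wt_d16")


@pytest.fixture(scope="session")
def endo_ko_report():
    stack, truth = vq.generate_phantom(vq.phantom_preset("endo_ko_d16", seed=5))
    return vq.analyze_vessel(stack, vessel_id="ek5", group="endo_ko_d16"), truth
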