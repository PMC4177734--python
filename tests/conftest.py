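"""Shared fixtures: small phantoms and scan geometries, rendered once."""

from __future__ import annotations

import numpy as np
import pytest

from octguide.phantom import PhantomParams, ScanGeometry, make_phantom, render_oct


@pytest.fixture(scope="session")
def flat_phantom():
    """Flat bone surface at z=0, flat boundary 400 µm deep: everything visible."""
    return make_phantom(
        PhantomParams(boundary_apex_depth=400.0, curvature_radius=np.inf,
                      extent=(2000.0, 2000.0))
    )


@pytest.fixture(scope="session")
def deep_phantom():
    """Boundary 1200 µm deep: far beyond the ~0.5 mm imaging range."""
    return make_phantom(
        PhantomParams(boundary_apex_depth=1200.0, curvature_radius=np.inf,
                      extent=(2000.0, 2000.0))
    )


@pytest.fixture(scope="session")
def small_geom():
    return ScanGeometry(fov=(1000.0, 1000.0), origin=(500.0, 500.0),
                        z_range=(-60.0, 900.0))


@pytest.fixture(scope="session")
def small_geom_clean():
    """Same field, no speckle, no noise floor."""
    return ScanGeometry(fov=(1000.0, 1000.0), origin=(500.0, 500.0),
                        z_range=(-60.0, 900.0), noise_floor=0.0, speckle=False)


@pytest.fixture(scope="session")
def flat_volume(flat_phantom, small_geom):
    return render_oct(flat_phantom, small_geom, seed=11)


@pytest.fixture(scope="session")
def flat_volume_clean(flat_phantom, small_geom_clean):
    return render_oct(flat_phantom, small_geom_clean, seed=0)
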