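import numpy as np
import pytest
from hypothesis import settings

from dvhkit.dvh import rasterize_structure
from dvhkit.phantom import PhantomSpec, make_phantom_plan

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def falloff_spec():
    """Sphere target + concentric shell OAR, linear radial dose falloff."""
    return PhantomSpec(seed=42)


@pytest.fixture(scope="session")
def falloff_bundle(falloff_spec):
    return make_phantom_plan(falloff_spec)


@pytest.fixture(scope="session")
def uniform_spec():
    """Membership-consistent uniform plateau: the ideal plan."""
    return PhantomSpec(dose_model="uniform", seed=42)


@pytest.fixture(scope="session")
def uniform_bundle(uniform_spec):
    return make_phantom_plan(uniform_spec)


@pytest.fixture(scope="session")
def falloff_masks(falloff_bundle):
    grid = falloff_bundle.grids["PTV1"]
    return {
        s.name: rasterize_structure(s, grid, supersample=2)
        for s in falloff_bundle.structures
    }


def pip_ray_casting(rings, x: float, y: float) -> bool:
    """Independent even-odd point-in-polygon oracle (crossing number).

    Pure-Python ray casting along +x; used to cross-check the shapely-based
    rasterizer on small grids.
    """
    crossings = 0
    for ring in rings:
        n = len(ring)
        for i in range(n):
            x1, y1 = ring[i]
            x2, y2 = ring[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if x_cross > x:
                    crossings += 1
    return crossings % 2 == 1
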