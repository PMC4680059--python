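import numpy as np
import pytest

from cdi import atlas, coords, synthetic

SMALL_SHAPE = dict(n_slices=40, in_plane_shape=(96, 120))
HOTSPOT = (0.55, 0.35, 0.30, 0.30)


def make_locset(surface: str, box=(0.50, 0.30, 0.40, 0.40)) -> atlas.LocationSet:
    """An even 3x3 location grid over a (u0, v0, w, h) box."""
    u0, v0, w, h = box
    du, dv = w / 3, h / 3
    locations, cells = [], []
    for j in range(3):
        for i in range(3):
            cells.append((u0 + i * du, v0 + j * dv, du, dv))
            locations.append((u0 + (i + 0.5) * du, v0 + (j + 0.5) * dv))
    return atlas.LocationSet(surface=surface, locations=locations, cells=cells)


@pytest.fixture(scope="session")
def femur_phantom():
    spec = synthetic.PhantomSpec(surface="femur", base_thickness_mm=2.0, **SMALL_SHAPE)
    return synthetic.rasterize_phantom(spec)


@pytest.fixture(scope="session")
def tibia_phantom():
    spec = synthetic.PhantomSpec(surface="tibia", base_thickness_mm=1.8, **SMALL_SHAPE)
    return synthetic.rasterize_phantom(spec)


@pytest.fixture(scope="session")
def femur_frame(femur_phantom):
    return coords.build_surface_frame(femur_phantom.volume, "femur")


@pytest.fixture(scope="session")
def tibia_frame(tibia_phantom):
    return coords.build_surface_frame(tibia_phantom.volume, "tibia")


@pytest.fixture(scope="session")
def posterior_locsets():
    return {s: make_locset(s) for s in ("femur", "tibia")}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
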