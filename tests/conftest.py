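import numpy as np
import pytest

import renalvh as rv


@pytest.fixture(scope="session")
def healthy_spec():
    """Default-geometry healthy kidney at 80 µm (fast enough for a session)."""
    return rv.PhantomSpec(voxel_spacing_mm=0.08, seed=11)


@pytest.fixture(scope="session")
def healthy_phantom(healthy_spec):
    return rv.generate_kidney_phantom(healthy_spec)


@pytest.fixture(scope="session")
def healthy_report(healthy_phantom):
    grid, _ = healthy_phantom
    return rv.quantify_kidney(grid)


@pytest.fixture(scope="session")
def uuo_phantom(healthy_phantom):
    grid, labels = healthy_phantom
    path = rv.PathologySpec(kind="uuo", pelvis_dilation_factor=1.5,
                            medulla_retention=0.2, cortex_gv_shift=-536.0)
    return rv.apply_pathology(grid, labels, path, seed=99)


def make_sphere_mask(radius_mm: float, spacing_mm: float, margin_mm: float = 0.3):
    n = int(np.ceil(2 * (radius_mm + margin_mm) / spacing_mm))
    c = n * spacing_mm / 2.0
    ax = (np.arange(n) + 0.5) * spacing_mm - c
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return d2 <= radius_mm ** 2
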