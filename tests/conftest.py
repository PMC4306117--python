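import numpy as np
import pytest

from plaquemorph import synthetic as syn


def digitised_sphere(radius_vox: float, pad: int = 3) -> np.ndarray:
    """Binary mask of a sphere of the given radius in voxel units."""
    n = int(2 * radius_vox + 2 * pad)
    c = (n - 1) / 2
    z, y, x = np.mgrid[:n, :n, :n]
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2


@pytest.fixture(scope="session")
def small_phantom():
    """3 spheres + 1 sheet + 1 irregular agglomerate in a 120^3 grid, noiseless."""
    vs = 15.5
    spheres = [
        syn.SphereSpec("s0", (400.0, 400.0, 400.0), 150.0),
        syn.SphereSpec("s1", (400.0, 1200.0, 400.0), 200.0),
        syn.SphereSpec("s2", (1200.0, 400.0, 1300.0), 120.0),
    ]
    sheet = syn.SheetSpec("sheet", (900.0, 1200.0, 600.0), 900.0, 400.0, 80.0)
    lobes = tuple(
        ((500.0 + 120.0 * i, 1350.0, 1250.0 + 60.0 * i), 200.0) for i in range(4)
    )
    irregular = syn.IrregularSpec("agg", lobes)
    spec = syn.PhantomSpec(
        grid_shape=(120, 120, 120),
        voxel_size_um=vs,
        inclusions=tuple(spheres) + (sheet, irregular),
        noise_sd=0.0,
        seed=7,
    )
    volume, truth = syn.generate_phantom_volume(spec)
    return spec, volume, truth
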