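import numpy as np
import pytest

from cellshape3d import (
    LabeledVolume,
    SyntheticTissueSpec,
    build_topology_tables,
    generate_prism_tissue,
    generate_scutoid_tissue,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def prism_tissue():
    """Columnar Voronoi tissue (cells taller than wide) with ground truth."""
    spec = SyntheticTissueSpec(shape=(40, 90, 90), n_seeds=18, rng_seed=7)
    return generate_prism_tissue(spec)


@pytest.fixture(scope="session")
def prism_topology(prism_tissue):
    vol, _ = prism_tissue
    return build_topology_tables(vol)


@pytest.fixture(scope="session")
def scutoid_tissue():
    spec = SyntheticTissueSpec(
        shape=(16, 100, 100), n_seeds=20, rng_seed=3, pattern="scutoid"
    )
    return generate_scutoid_tissue(spec)


@pytest.fixture(scope="session")
def scutoid_topology(scutoid_tissue):
    vol, _ = scutoid_tissue
    return build_topology_tables(vol)


@pytest.fixture()
def two_cuboids():
    """Two 8×10×10 cuboids sharing a 8×10 wall at x = 10."""
    labels = np.zeros((8, 10, 20), dtype=np.int32)
    labels[:, :, :10] = 1
    labels[:, :, 10:] = 2
    return LabeledVolume(labels, (1.0, 1.0, 1.0))


@pytest.fixture()
def three_strips():
    """Three vertical strips 1|2|3: junctions are straight vertical lines."""
    labels = np.zeros((12, 9, 9), dtype=np.int32)
    labels[:, :3, :] = 1
    labels[:, 3:6, :] = 2
    labels[:, 6:, :] = 3
    return LabeledVolume(labels, (1.0, 1.0, 1.0))


@pytest.fixture()
def triple_junction():
    """Three cells meeting along one vertical line at (y, x) = (6, 6)."""
    labels = np.zeros((10, 12, 12), dtype=np.int32)
    labels[:, :6, :6] = 1
    labels[:, :6, 6:] = 2
    labels[:, 6:, :] = 3
    return LabeledVolume(labels, (1.0, 1.0, 1.0))


def cube_mask(side: int, pad: int = 1):
    """A padded cubic CellMask of the given side length."""
    from cellshape3d import CellMask

    mask = np.zeros((side + 2 * pad,) * 3, dtype=bool)
    mask[pad:-pad, pad:-pad, pad:-pad] = True
    return CellMask(cell_id=1, mask=mask, offset=(-pad, -pad, -pad), padded=True)


def ball_mask(radius: int):
    from cellshape3d import CellMask

    n = 2 * radius + 3
    c = n // 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return CellMask(cell_id=1, mask=mask, offset=(0, 0, 0), padded=True)
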