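"""Shared fixtures: small phantom cases and analytic mask builders."""

import numpy as np
import pytest

from dosecast import MaskVolume
from dosecast.phantom import PhantomParams, generate_case


#: small grid that still contains the full default anatomy (288 mm transaxially)
SMALL = dict(shape=(44, 64, 64), spacing=(4.5, 4.5, 4.5))


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(**SMALL, seed=3)


@pytest.fixture(scope="session")
def small_case(small_params):
    """One deterministic phantom case on the small grid."""
    return generate_case(small_params, "case0")


@pytest.fixture(scope="session")
def small_pair(small_params):
    """Two anatomically different phantom cases on a common grid."""
    from dosecast.phantom import _sample_params
    rng = np.random.default_rng(11)
    other = _sample_params(small_params, rng)
    return (generate_case(small_params, "fixed"),
            generate_case(other, "floating"))


def make_mask(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), label="m"):
    return MaskVolume(np.asarray(arr, dtype=np.uint8), spacing, origin, label=label)


def ellipsoid_mask(semiaxes, rotation=None, center=(0.0, 0.0, 0.0),
                   spacing=1.0, n=96, bump=0.0, label="m"):
    """Analytically rasterised (optionally rotated/translated) ellipsoid.

    ``bump`` > 0 adds a smaller ellipsoid offset along the local +x axis,
    breaking the point symmetry so odd-order moments are nonzero.
    """
    R = np.eye(3) if rotation is None else np.asarray(rotation)
    coords = (np.arange(n) - (n - 1) / 2) * spacing
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([xx - center[0], yy - center[1], zz - center[2]], axis=-1)
    local = pts @ R  # columns of R = world directions of the local axes
    a, b, c = semiaxes
    q = (local[..., 0] / a) ** 2 + (local[..., 1] / b) ** 2 + (local[..., 2] / c) ** 2
    inside = q <= 1.0
    if bump > 0:
        qb = (((local[..., 0] - a) / (bump * a)) ** 2
              + (local[..., 1] / (bump * b)) ** 2
              + (local[..., 2] / (bump * c)) ** 2)
        inside |= qb <= 1.0
    return MaskVolume(inside.astype(np.uint8), (spacing,) * 3,
                      (-(n - 1) / 2 * spacing,) * 3, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
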