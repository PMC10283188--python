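import numpy as np
import pytest

from magnetoguide import forces, geometry
from magnetoguide.magnetostatics import MU0


def surface_charge_field(bounds, M_vec, point_m, n=200):
    """Independent oracle for the prism stray field: Gauss-Legendre quadrature
    of the magnetic surface charges ±M_a on the faces perpendicular to each
    magnetization component."""
    g, w = np.polynomial.legendre.leggauss(n)
    point_m = np.asarray(point_m, dtype=float)
    B = np.zeros(3)
    axes = [0, 1, 2]
    for a in range(3):
        Ma = M_vec[a]
        if Ma == 0.0:
            continue
        u_ax, v_ax = [ax for ax in axes if ax != a]
        (u1, u2), (v1, v2) = bounds[u_ax], bounds[v_ax]
        us = 0.5 * (u2 - u1) * g + 0.5 * (u1 + u2)
        vs = 0.5 * (v2 - v1) * g + 0.5 * (v1 + v2)
        wu = 0.5 * (u2 - u1) * w
        wv = 0.5 * (v2 - v1) * w
        UU, VV = np.meshgrid(us, vs, indexing="ij")
        W = np.outer(wu, wv)
        for face, sign in ((bounds[a][1], +1.0), (bounds[a][0], -1.0)):
            src = np.zeros((n, n, 3))
            src[..., u_ax] = UU
            src[..., v_ax] = VV
            src[..., a] = face
            d = point_m[None, None, :] - src
            r3 = np.sum(d * d, axis=2) ** 1.5
            B += sign * Ma * np.tensordot(W / r3, d, axes=([0, 1], [0, 1]))
    return MU0 / (4 * np.pi) * B


@pytest.fixture(scope="session")
def permalloy_bar():
    """200 × 50 µm², 74 nm permalloy bar, long axis and magnetization along y
    (poles at y = ±100 µm)."""
    return geometry.single_bar()


@pytest.fixture(scope="session")
def bar_force_map(permalloy_bar):
    """Linear-response force map 2 µm above the bar, 1 µm grid."""
    return forces.pattern_force_map(permalloy_bar, z_um=2.0, spacing_um=1.0)


@pytest.fixture(scope="session")
def bar_hot_spots(bar_force_map):
    return forces.find_hot_spots(bar_force_map)
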