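"""Shared fixtures: all geometry is generated programmatically and the
expensive pipeline stages (cMCF + IRF fit) are cached per session."""

import warnings

import numpy as np
import pytest

from flowshape.fixtures import make_ellipsoid, make_icosphere, make_protrusion_sphere
from flowshape.harmonics import irf_fit
from flowshape.spheremap import cmcf, curvature_function


@pytest.fixture(autouse=True)
def _quiet_cmcf_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cMCF did not reach")
        yield


@pytest.fixture(scope="session")
def ico2():
    return make_icosphere(2)


@pytest.fixture(scope="session")
def ico3():
    return make_icosphere(3)


@pytest.fixture(scope="session")
def ico4():
    return make_icosphere(4)


@pytest.fixture(scope="session")
def ellipsoid():
    return make_ellipsoid(2.0, 1.0, 1.0, subdiv=3)


@pytest.fixture(scope="session")
def ellipsoid_pipeline(ellipsoid):
    """(smap, rho, coeffs at lmax 24) of the 2:1:1 ellipsoid."""
    smap, diag = cmcf(ellipsoid)
    assert diag.converged
    rho = curvature_function(ellipsoid, smap)
    return smap, rho, irf_fit(rho, lmax=24)


@pytest.fixture(scope="session")
def sphere_pipeline(ico3):
    smap, diag = cmcf(ico3)
    assert diag.converged
    rho = curvature_function(ico3, smap)
    return smap, rho, irf_fit(rho, lmax=24)


@pytest.fixture(scope="session")
def protrusion_fixture():
    """Sphere with one protrusion (length = radius) plus ground-truth labels."""
    return make_protrusion_sphere(1.0, width=0.3, subdiv=3, n_protrusions=1, seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230616)


def make_torus(n_major=24, n_minor=12, R=2.0, r=0.7):
    """Parametric torus triangulation (genus 1) built by hand."""
    from flowshape.mesh import TriangleMesh

    u = np.arange(n_major) * 2 * np.pi / n_major
    v = np.arange(n_minor) * 2 * np.pi / n_minor
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (R + r * np.cos(vv)) * np.cos(uu)
    y = (R + r * np.cos(vv)) * np.sin(uu)
    z = r * np.sin(vv)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    faces = []
    for i in range(n_major):
        for j in range(n_minor):
            a = i * n_minor + j
            b = ((i + 1) % n_major) * n_minor + j
            c = i * n_minor + (j + 1) % n_minor
            d = ((i + 1) % n_major) * n_minor + (j + 1) % n_minor
            faces += [[a, b, d], [a, d, c]]
    return TriangleMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def torus():
    return make_torus()
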