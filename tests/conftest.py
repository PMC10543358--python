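"""Shared fixtures: analytic test surfaces and a reusable pRF search grid."""

import numpy as np
import pytest

from linetarget.prf import CandidateGrid, HRFModel, PRFGridSpec, build_bar_design
from linetarget.surface import SurfaceMesh


def icosphere(radius: float, subdivisions: int = 3) -> SurfaceMesh:
    """Icosahedron-subdivision sphere with outward-wound faces."""
    t = (1 + 5**0.5) / 2
    verts = np.array(
        [[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
         [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
         [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float)
    faces = np.array(
        [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
         [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
         [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
         [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]])
    for _ in range(subdivisions):
        verts = list(verts)
        cache: dict = {}
        new_faces = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                verts.append((np.asarray(verts[a]) + verts[b]) / 2)
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.array(new_faces)
        verts = np.array(verts)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return SurfaceMesh(verts, faces)


def cylinder_patch(radius: float, n_theta: int = 80, n_z: int = 40,
                   height: float = 30.0) -> SurfaceMesh:
    """Open half-cylinder patch with outward-wound faces."""
    th = np.linspace(0, np.pi, n_theta)
    z = np.linspace(0, height, n_z)
    TH, Z = np.meshgrid(th, z, indexing="ij")
    verts = np.column_stack(
        [radius * np.cos(TH).ravel(), radius * np.sin(TH).ravel(), Z.ravel()])
    idx = np.arange(n_theta * n_z).reshape(n_theta, n_z)
    faces = []
    for i in range(n_theta - 1):
        for j in range(n_z - 1):
            faces.append([idx[i, j], idx[i + 1, j], idx[i + 1, j + 1]])
            faces.append([idx[i, j], idx[i + 1, j + 1], idx[i, j + 1]])
    return SurfaceMesh(verts, np.array(faces))


def flat_grid_mesh(n: int = 10, spacing: float = 1.0) -> SurfaceMesh:
    """Planar z=0 sheet with counter-clockwise winding (normals +z)."""
    x = np.arange(n) * spacing
    X, Y = np.meshgrid(x, x, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    idx = np.arange(n * n).reshape(n, n)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            faces.append([idx[i, j], idx[i + 1, j], idx[i + 1, j + 1]])
            faces.append([idx[i, j], idx[i + 1, j + 1], idx[i, j + 1]])
    return SurfaceMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def small_design():
    """Fast whole-brain-style bar design for fitting tests (TR 1.5 s)."""
    return build_bar_design([0.0, 45.0, 90.0, 135.0], directions=(1, -1),
                            bar_widths=(1.25,), grid_extent=10.0, step=0.25,
                            tr=1.5, blank_s=15.0, n_pix=30)


@pytest.fixture(scope="session")
def small_hrf(small_design):
    return HRFModel.double_gamma(small_design.tr)


@pytest.fixture(scope="session")
def small_grid(small_design, small_hrf):
    spec = PRFGridSpec.from_design(small_design)
    return CandidateGrid(small_design, small_hrf, spec)


@pytest.fixture(scope="session")
def line_design():
    """The line-session design (TR 0.105 s, 2 ori x 2 dir x 2 widths)."""
    from linetarget.pipeline import default_line_design

    return default_line_design()


@pytest.fixture(scope="session")
def line_grid(line_design):
    hrf = HRFModel.double_gamma(line_design.tr)
    spec = PRFGridSpec.from_design(line_design)
    return CandidateGrid(line_design, hrf, spec)
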