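"""Shared fixtures: small synthetic meshes, measurement factories, oracles."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from craniosort.osteometry import C1_MEASUREMENTS, OC_MEASUREMENTS, MeasurementSet
from craniosort.registration import RoiMesh


def make_individual(individual_id: str, rng: np.random.Generator,
                    sex: str = "unknown") -> MeasurementSet:
    """A random but anatomically plausible measurement record."""
    oc = {k: float(rng.uniform(8.0, 55.0)) for k in OC_MEASUREMENTS}
    c1 = {k: float(rng.uniform(8.0, 55.0)) for k in C1_MEASUREMENTS}
    return MeasurementSet(individual_id=individual_id, sex=sex, oc=oc, c1=c1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def individuals(rng):
    return [make_individual(f"id{i}", rng) for i in range(5)]


def planar_grid(nx: int = 6, ny: int = 6, z: float = 0.0,
                spacing: float = 1.0) -> trimesh.Trimesh:
    """A flat triangulated grid in the z = const plane."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing,
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(nx * ny, z)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


@pytest.fixture
def grid_roi():
    return RoiMesh(planar_grid(), provenance="test")


def random_rotation(rng: np.random.Generator, max_angle: float = np.pi) -> np.ndarray:
    """Uniform-axis random rotation matrix with angle up to ``max_angle``."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def point_triangle_distance(p, a, b, c) -> float:
    """Scalar reference distance from a point to one triangle.

    Independent re-derivation (region classification via barycentric
    clamping) used as the exhaustive oracle against the vectorised
    library path.
    """
    p, a, b, c = (np.asarray(x, dtype=float) for x in (p, a, b, c))
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(p - a))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(p - b))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + v * ab)))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(p - c))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + w * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + w * (c - b))))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return float(np.linalg.norm(p - (a + v * ab + w * ac)))


def brute_force_surface_distance(points: np.ndarray,
                                 mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-point nearest-triangle scan over every face (the exhaustive oracle)."""
    verts = np.asarray(mesh.vertices, dtype=float)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = min(point_triangle_distance(p, *verts[f]) for f in mesh.faces)
    return out
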