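"""Rigid superimposition of articular-surface patches.

The 3D screening arm registers the occipital-condyle patch (the moving
surface) onto the atlas superior-articular-facet patch in two stages:

1. a closed-form least-squares fit (Kabsch) of the four labelled edge
   landmarks per facet — anterior, posterior, lateral, medial — which gives
   the initial orientation;
2. iterative closest point (ICP) refinement: alternate nearest
   point-on-surface correspondence and the rigid least-squares update until
   the RMS distance change falls below tolerance.

The discrepancy between the registered surfaces is summarised by the RMS,
minimum, maximum and SD of the per-vertex unsigned distances from the
transformed moving vertices to the fixed triangulated surface; the RMS is
the screening statistic.  Both stages are strictly rigid: no scaling and no
reflection, since both patches are real-size scans in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from trimesh.proximity import closest_point_naive

__all__ = [
    "RoiMesh",
    "LandmarkSet",
    "RigidTransform",
    "DistanceSummary",
    "Superimposition",
    "kabsch",
    "landmark_align",
    "icp_refine",
    "distance_summary",
    "crop_roi",
    "export_colormap",
    "read_colormap",
]

LANDMARK_LABELS = ("anterior", "posterior", "lateral", "medial")
FACETS = ("left", "right")


@dataclass
class RoiMesh:
    """A bilateral articular-surface patch (mm units).

    Wraps a :class:`trimesh.Trimesh` and records which facet (left or
    right) each vertex belongs to plus the anatomical provenance.  The two
    facets are kept in a single mesh at their original separation, so the
    inter-facet geometry takes part in the superimposition.
    """

    mesh: trimesh.Trimesh
    side_labels: np.ndarray | None = None
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.mesh.vertices, dtype=float)
        f = np.asarray(self.mesh.faces)
        if len(v) < 3:
            raise ValueError("mesh must have at least 3 vertices")
        if not np.isfinite(v).all():
            raise ValueError("mesh vertices contain non-finite coordinates")
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("faces index out-of-range vertices")
        if self.side_labels is not None:
            self.side_labels = np.asarray(self.side_labels)
            if len(self.side_labels) != len(v):
                raise ValueError("side_labels length must match vertex count")
            present = set(np.unique(self.side_labels))
            if not present <= {"left", "right"}:
                raise ValueError(f"side labels must be left/right, got {present}")
            if present != {"left", "right"}:
                raise ValueError("bilateral patch requires both facets present")

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices, dtype=float)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)

    def transformed(self, transform: "RigidTransform") -> "RoiMesh":
        """A copy with the rigid transform applied to the vertices."""
        m = self.mesh.copy()
        m.vertices = transform.apply(self.vertices)
        return RoiMesh(m, side_labels=None if self.side_labels is None else self.side_labels.copy(),
                       provenance=self.provenance)


@dataclass(frozen=True)
class LandmarkSet:
    """Four labelled edge points per facet (anterior/posterior/lateral/medial), mm."""

    facets: Mapping[str, Mapping[str, Sequence[float]]]

    def __post_init__(self) -> None:
        for facet, pts in self.facets.items():
            if facet not in FACETS:
                raise ValueError(f"unknown facet {facet!r}; expected {FACETS}")
            if set(pts) != set(LANDMARK_LABELS):
                raise ValueError(
                    f"facet {facet!r} must carry exactly the labels {LANDMARK_LABELS}, got {sorted(pts)}"
                )
            for label, p in pts.items():
                arr = np.asarray(p, dtype=float)
                if arr.shape != (3,) or not np.isfinite(arr).all():
                    raise ValueError(f"landmark {facet}/{label} must be a finite 3-vector")
        if len(self.facets) == 0:
            raise ValueError("landmark set is empty")

    def keys(self) -> list[tuple[str, str]]:
        return [(facet, label) for facet in sorted(self.facets) for label in LANDMARK_LABELS]

    def points(self, keys: Iterable[tuple[str, str]] | None = None) -> np.ndarray:
        """Stack landmarks as an (m, 3) array in a deterministic key order."""
        if keys is None:
            keys = self.keys()
        return np.array([self.facets[f][l] for f, l in keys], dtype=float)

    def transformed(self, transform: "RigidTransform") -> "LandmarkSet":
        out = {
            facet: {label: transform.apply(np.asarray(p, dtype=float)[None, :])[0].tolist()
                    for label, p in pts.items()}
            for facet, pts in self.facets.items()
        }
        return LandmarkSet(out)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1, no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        R = self.rotation @ other.rotation
        # re-project to the nearest rotation so float drift never violates invariants
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1
            R = U @ Vt
        return RigidTransform(R, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class DistanceSummary:
    """Per-vertex unsigned distance field and its RMS / min / max / SD (mm)."""

    rms: float
    min: float
    max: float
    sd: float
    per_vertex: np.ndarray

    @classmethod
    def from_distances(cls, distances: np.ndarray) -> "DistanceSummary":
        d = np.asarray(distances, dtype=float).ravel()
        if d.size == 0:
            raise ValueError("empty distance field")
        if (d < 0).any():
            raise ValueError("distances must be unsigned")
        return cls(
            rms=float(np.sqrt(np.mean(d * d))),
            min=float(d.min()),
            max=float(d.max()),
            sd=float(d.std(ddof=0)),
            per_vertex=d,
        )


@dataclass(frozen=True)
class Superimposition:
    """One registered occipital-condyle / atlas-facet pair."""

    oc_id: str
    c1_id: str
    transform: RigidTransform
    summary: DistanceSummary
    converged: bool = True
    n_iterations: int = 0
    rms_trace: tuple[float, ...] = ()

    @property
    def label(self) -> str:
        return "match" if self.oc_id == self.c1_id else "mismatch"


def kabsch(src_points: np.ndarray, dst_points: np.ndarray) -> RigidTransform:
    """Closed-form rigid least-squares fit of matched point sets.

    Returns the proper rigid transform minimising
    ``sum_i || R p_i + t - q_i ||^2`` (no scaling, no reflection).

    Raises
    ------
    ValueError
        If fewer than 3 points are given or the source points are
        collinear (the rotation is then underdetermined).
    """
    p = np.asarray(src_points, dtype=float)
    q = np.asarray(dst_points, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must be matching (m, 3) arrays")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 matched points")
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    pc, qc = p - cp, q - cq
    # collinear source points leave a free rotation about the line
    if np.linalg.matrix_rank(pc, tol=1e-9 * max(1.0, np.abs(pc).max())) < 2:
        raise ValueError("source points are collinear; rotation underdetermined")
    H = pc.T @ qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)


def landmark_align(src: LandmarkSet, dst: LandmarkSet) -> RigidTransform:
    """Stage-one registration from label-matched edge landmarks.

    Matches landmarks by (facet, label) key and returns the rigid transform
    carrying the source landmarks onto the destination ones in the
    least-squares sense.
    """
    src_keys = set(src.keys())
    dst_keys = set(dst.keys())
    if src_keys != dst_keys:
        raise ValueError(f"landmark sets differ: {sorted(src_keys ^ dst_keys)}")
    keys = sorted(src_keys)
    return kabsch(src.points(keys), dst.points(keys))


def _surface_distances(points: np.ndarray, dst: RoiMesh) -> tuple[np.ndarray, np.ndarray]:
    """Nearest point on the destination surface for each query point.

    Uses an exact all-pairs point-to-triangle query (the destination
    patches are small, a few hundred faces, so brute force is both exact
    and fast).  Falls back to vertex distances for meshes without faces.
    """
    if len(dst.faces) == 0:
        tree = cKDTree(dst.vertices)
        dist, idx = tree.query(points)
        return dst.vertices[idx], np.asarray(dist, dtype=float)
    closest, dist, _ = closest_point_naive(dst.mesh, points)
    return np.asarray(closest, dtype=float), np.asarray(dist, dtype=float)


def distance_summary(src: RoiMesh, dst: RoiMesh, transform: RigidTransform,
                     mode: str = "surface") -> DistanceSummary:
    """Unsigned distance field from transformed source vertices to the target.

    ``mode="surface"`` (default) measures vertex-to-nearest-surface-point
    (point-to-triangle) distance, which is robust when the two scans have
    different mesh resolutions; ``mode="vertex"`` measures
    vertex-to-nearest-vertex distance for sensitivity analysis.
    """
    pts = transform.apply(src.vertices)
    if pts.shape[0] == 0:
        raise ValueError("source mesh has no vertices")
    if mode == "surface":
        _, dist = _surface_distances(pts, dst)
    elif mode == "vertex":
        tree = cKDTree(dst.vertices)
        dist, _ = tree.query(pts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceSummary.from_distances(dist)


def icp_refine(
    src: RoiMesh,
    dst: RoiMesh,
    init: RigidTransform | None = None,
    max_iterations: int = 100,
    convergence_tolerance: float = 1e-6,
    mode: str = "surface",
    oc_id: str = "src",
    c1_id: str = "dst",
) -> Superimposition:
    """Stage-two registration: iterative closest point refinement.

    Starting from ``init`` (typically the landmark fit), alternates
    (a) nearest point-on-surface correspondence for every transformed
    source vertex and (b) the closed-form rigid update to those
    correspondences.  Each update minimises the distance to the current
    footpoints, so the RMS is non-increasing across iterations; the loop
    stops when the RMS change drops below ``convergence_tolerance`` (mm)
    or after ``max_iterations``.  Non-convergence is reported through the
    ``converged`` flag, never as an exception.
    """
    if init is None:
        init = RigidTransform.identity()
    if max_iterations < 0:
        raise ValueError("max_iterations must be >= 0")
    src_v = src.vertices
    if src_v.shape[0] < 3:
        raise ValueError("source mesh too small to register")

    transform = init
    pts = transform.apply(src_v)
    if mode == "vertex":
        tree = cKDTree(dst.vertices)

        def correspond(p):
            dist, idx = tree.query(p)
            return dst.vertices[idx], np.asarray(dist, dtype=float)
    elif mode == "surface":
        def correspond(p):
            return _surface_distances(p, dst)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    closest, dist = correspond(pts)
    rms = float(np.sqrt(np.mean(dist**2)))
    trace = [rms]
    converged = max_iterations == 0
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        # absolute re-fit from the untransformed source avoids compounding drift
        transform = kabsch(src_v, closest)
        pts = transform.apply(src_v)
        closest, dist = correspond(pts)
        new_rms = float(np.sqrt(np.mean(dist**2)))
        trace.append(new_rms)
        if abs(rms - new_rms) < convergence_tolerance:
            rms = new_rms
            converged = True
            break
        rms = new_rms
    return Superimposition(
        oc_id=oc_id,
        c1_id=c1_id,
        transform=transform,
        summary=DistanceSummary.from_distances(dist),
        converged=converged,
        n_iterations=iterations,
        rms_trace=tuple(trace),
    )


def crop_roi(mesh: trimesh.Trimesh, contour: np.ndarray,
             closed_tol: float = 1e-6, provenance: str = "unknown",
             side_labels: np.ndarray | None = None) -> RoiMesh:
    """Cut an articular-surface patch out of a full bone scan.

    The analyst traces a closed polyline on the surface around the facet;
    the mesh vertices are projected onto the best-fit plane of that contour
    and kept when they fall inside the projected polygon.  Faces survive
    when all three of their vertices survive.
    """
    from matplotlib.path import Path

    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 3:
        raise ValueError("contour must be an (m >= 3, 3) polyline")
    if np.linalg.norm(c[0] - c[-1]) > closed_tol:
        raise ValueError("contour must be closed (first point ~= last point)")
    ring = c[:-1]
    centroid = ring.mean(axis=0)
    centered = ring - centroid
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("contour points are collinear; no plane defined")
    axes = Vt[:2]  # in-plane basis of the best-fit plane

    poly2d = centered @ axes.T
    verts = np.asarray(mesh.vertices, dtype=float)
    verts2d = (verts - centroid) @ axes.T
    inside = Path(poly2d).contains_points(verts2d)
    if not inside.any():
        raise ValueError("contour selects no vertices")

    index_map = -np.ones(len(verts), dtype=int)
    index_map[inside] = np.arange(inside.sum())
    faces = np.asarray(mesh.faces)
    keep_faces = inside[faces].all(axis=1) if len(faces) else np.zeros(0, bool)
    new_faces = index_map[faces[keep_faces]] if len(faces) else np.zeros((0, 3), int)
    sub = trimesh.Trimesh(vertices=verts[inside], faces=new_faces, process=False)
    labels = None if side_labels is None else np.asarray(side_labels)[inside]
    return RoiMesh(sub, side_labels=labels, provenance=provenance)


def export_colormap(superimposition: Superimposition, src: RoiMesh, path,
                    scale: tuple[float, float] = (0.0, 1.0),
                    cmap: str = "jet") -> None:
    """Write the registered moving mesh with its per-vertex distance field.

    Produces an ASCII PLY carrying the transformed vertices, a ``quality``
    property holding the distance (clipped to ``scale``) and an RGB colour
    per vertex mapped through ``cmap`` — the colour-coded congruency map a
    practitioner inspects before reading the RMS.
    """
    import matplotlib

    lo, hi = float(scale[0]), float(scale[1])
    if lo >= hi:
        raise ValueError("scale min must be below scale max")
    d = np.clip(superimposition.summary.per_vertex, lo, hi)
    if d.shape[0] != len(src.vertices):
        raise ValueError("distance field length does not match mesh vertex count")
    m = src.mesh.copy()
    m.vertices = superimposition.transform.apply(src.vertices)
    m.vertex_attributes["quality"] = d.astype(np.float32)
    colors = matplotlib.colormaps[cmap]((d - lo) / (hi - lo))
    m.visual.vertex_colors = (colors * 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(m.export(file_type="ply", encoding="ascii"))


def read_colormap(path) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Read back a colormap PLY, returning the mesh and the quality scalars."""
    m = trimesh.load(path, file_type="ply", process=False)
    raw = m.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    if raw is None or "quality" not in raw:
        raise ValueError(f"{path} carries no per-vertex quality field")
    return m, np.asarray(raw["quality"], dtype=float).ravel()
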