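r"""Landmark- and mesh-based measurement of the nine calcaneal parameters.

The measurement substrate is a set of six surface landmarks:

========  ====================================================================
A         highest point of the posterior articular facet
B         bottom of the posterior facet at the lateral surface, where it
          meets the anterior process
C         highest point of the calcaneocuboid joint
D         lowest point of the calcaneocuboid joint
E         most posterior point of the calcaneal tuberosity
F         highest point on the superior edge of the calcaneal tuberosity
========  ====================================================================

Two points are constructed: G, the midpoint of C and D, and H, the foot of
the perpendicular from A onto the calcaneal axis (the line through G and E).
The seven landmark parameters are then

* LCA = \|GE\|  (length of the calcaneal axis)
* HPF = \|AH\|  (height of the posterior facet, point-to-line distance)
* LPF = \|AB\|, LAP = \|BC\|, HAP = \|CD\|
* GA  = ∠ABC   (Gissane's critical angle, at vertex B)
* BA  = 180° − ∠CAF  (Böhler's tuber angle)

Facet areas (APF, AMF) are measured on a triangulated bone-surface mesh
within an operator-supplied closed boundary; see :func:`facet_area`.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .errors import BoundaryError, DataError, GeometryError, MissingLandmarkError
from .params import MorphometricRecord

__all__ = [
    "LandmarkSet",
    "FacetBoundary",
    "distance",
    "axis_and_height",
    "gissane_angle",
    "bohler_angle",
    "facet_area",
    "measure_all",
    "read_landmarks",
    "write_landmarks",
    "read_boundaries",
    "write_boundaries",
]

LANDMARK_NAMES = ("A", "B", "C", "D", "E", "F")

_MM2_PER_CM2 = 100.0


def _point(p, name: str) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise GeometryError(f"landmark {name} must be a finite 3-vector, got {p!r}")
    return a


@dataclass(frozen=True)
class LandmarkSet:
    """The six input landmarks A–F plus the derived points G and H.

    G and H are computed, never stored, so the invariants G = (C+D)/2 and
    AH ⟂ GE hold exactly by construction.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        pts = {}
        for name in LANDMARK_NAMES:
            object.__setattr__(self, name, _point(getattr(self, name), name))
            pts[name] = getattr(self, name)
        names = list(pts)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.array_equal(pts[a], pts[b]):
                    raise GeometryError(f"landmarks {a} and {b} coincide")

    @property
    def G(self) -> np.ndarray:
        """Midpoint of the calcaneocuboid-joint landmarks C and D."""
        return 0.5 * (self.C + self.D)

    @property
    def H(self) -> np.ndarray:
        """Foot of the perpendicular from A onto the calcaneal axis GE."""
        _, H, _, _ = axis_and_height(self.A, self.C, self.D, self.E)
        return H

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in LANDMARK_NAMES}

    def transformed(self, rotation=None, translation=None, scale: float = 1.0
                    ) -> "LandmarkSet":
        """Return a similarity-transformed copy (scale, then rotate, then shift)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return LandmarkSet(**{
            name: R @ (scale * getattr(self, name)) + t for name in LANDMARK_NAMES
        })


@dataclass(frozen=True)
class FacetBoundary:
    """A closed loop of points marking an articular facet on the bone surface.

    ``points`` is an ordered loop (first and last are implicitly joined);
    ``seed`` is one point inside the region the loop encloses; ``label``
    names the facet ("posterior" or "middle").
    """

    points: np.ndarray
    seed: np.ndarray
    label: str

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or not np.all(np.isfinite(pts)):
            raise DataError("boundary points must be an (n, 3) array of finite mm coordinates")
        # drop an explicitly repeated closing point
        if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise DataError("a facet boundary needs at least 3 distinct points")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "seed", _point(self.seed, "boundary seed"))
        if any(np.array_equal(self.seed, p) for p in pts):
            raise DataError("boundary seed must not lie on the boundary loop")
        if self.label not in ("posterior", "middle"):
            raise DataError(f"facet label must be 'posterior' or 'middle', got {self.label!r}")


# ---------------------------------------------------------------------------
# elementary measurements
# ---------------------------------------------------------------------------

def distance(p, q) -> float:
    """Euclidean distance between two points in mm."""
    return float(np.linalg.norm(np.asarray(q, float) - np.asarray(p, float)))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between vectors in degrees, stable near 0° and 180°."""
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    return math.degrees(math.atan2(cross, dot))


def axis_and_height(A, C, D, E) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Calcaneal axis construction: returns (G, H, LCA, HPF).

    G = (C+D)/2; LCA = |GE|; H = orthogonal projection of A onto the
    infinite line through G and E (not clamped to the segment); HPF = |AH|.
    """
    A, C, D, E = (_point(p, n) for p, n in zip((A, C, D, E), "ACDE"))
    G = 0.5 * (C + D)
    axis = E - G
    lca = float(np.linalg.norm(axis))
    if lca == 0.0:
        raise GeometryError("degenerate calcaneal axis: G coincides with E")
    u = axis / lca
    w = A - G
    H = G + float(np.dot(w, u)) * u
    hpf = float(np.linalg.norm(A - H))
    return G, H, lca, hpf


def gissane_angle(A, B, C) -> float:
    """Gissane's critical angle ∠ABC in degrees: rays BA and BC meeting at B."""
    A, B, C = (_point(p, n) for p, n in zip((A, B, C), "ABC"))
    u, v = A - B, C - B
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise GeometryError("Gissane angle undefined: B coincides with A or C")
    return _angle_deg(u, v)


def bohler_angle(A, C, F) -> float:
    """Böhler's tuber angle in degrees, computed as 180° − ∠CAF."""
    A, C, F = (_point(p, n) for p, n in zip((A, C, F), "ACF"))
    u, v = C - A, F - A
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise GeometryError("Böhler angle undefined: A coincides with C or F")
    return 180.0 - _angle_deg(u, v)


# ---------------------------------------------------------------------------
# facet area on the surface mesh
# ---------------------------------------------------------------------------

def _vertex_adjacency(mesh: trimesh.Trimesh) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for a, b in mesh.edges_unique:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    for k in adj:
        adj[k].sort()  # deterministic BFS tie-break: lowest vertex index first
    return adj


def _shortest_edge_path(adj: Mapping[int, list[int]], src: int, dst: int
                        ) -> list[int]:
    """Unweighted shortest vertex path by BFS with sorted neighbour order."""
    if src == dst:
        return [src]
    parent: dict[int, Optional[int]] = {src: None}
    queue: deque[int] = deque([src])
    while queue:
        u = queue.popleft()
        for w in adj.get(u, ()):
            if w not in parent:
                parent[w] = u
                if w == dst:
                    path = [w]
                    while parent[path[-1]] is not None:
                        path.append(parent[path[-1]])  # type: ignore[arg-type]
                    return path[::-1]
                queue.append(w)
    raise BoundaryError(f"mesh vertices {src} and {dst} are not edge-connected")


def _seed_face(mesh: trimesh.Trimesh, tree: cKDTree, seed: np.ndarray) -> int:
    """Triangle nearest the seed point: incident faces of the nearest vertex,
    closest centroid, ties broken by lowest face index."""
    _, vid = tree.query(seed)
    faces = mesh.vertex_faces[int(vid)]
    faces = np.sort(faces[faces >= 0])
    centroids = mesh.triangles_center[faces]
    d = np.linalg.norm(centroids - seed, axis=1)
    return int(faces[int(np.argmin(d))])


def facet_area(mesh: trimesh.Trimesh, boundary: FacetBoundary,
               snap_tolerance: Optional[float] = None) -> float:
    """Area (cm²) of the mesh region enclosed by a facet boundary.

    The boundary points are snapped to their nearest mesh vertices (within
    ``snap_tolerance``, default 2× the mean edge length), consecutive snapped
    vertices are joined by unweighted shortest edge paths to form a closed
    edge cycle, and triangles are flood-filled across face adjacency from the
    triangle nearest the seed, never crossing a boundary edge. The returned
    value is the summed triangle area of the filled region.

    Raises :class:`BoundaryError` if a boundary point is too far from the
    mesh, the loop cannot be closed, or the fill leaks over the whole mesh.
    """
    if len(mesh.faces) == 0:
        raise BoundaryError("cannot measure a facet on an empty mesh")
    tree = cKDTree(mesh.vertices)
    tol = snap_tolerance if snap_tolerance is not None else 2.0 * float(
        mesh.edges_unique_length.mean())
    dists, idx = tree.query(boundary.points)
    too_far = dists > tol
    if np.any(too_far):
        worst = int(np.argmax(dists))
        raise BoundaryError(
            f"boundary point {worst} of facet '{boundary.label}' is "
            f"{dists[worst]:.2f} mm from the mesh (tolerance {tol:.2f} mm)")
    snapped: list[int] = []
    for v in idx:
        v = int(v)
        if not snapped or snapped[-1] != v:
            snapped.append(v)
    if len(snapped) > 1 and snapped[0] == snapped[-1]:
        snapped.pop()
    if len(snapped) < 3:
        raise BoundaryError(
            f"facet '{boundary.label}': boundary collapses to fewer than 3 "
            "distinct mesh vertices after snapping")

    adj = _vertex_adjacency(mesh)
    boundary_edges: set[tuple[int, int]] = set()
    for i, src in enumerate(snapped):
        dst = snapped[(i + 1) % len(snapped)]
        path = _shortest_edge_path(adj, src, dst)
        for a, b in zip(path[:-1], path[1:]):
            boundary_edges.add((min(a, b), max(a, b)))
    if not boundary_edges:
        raise BoundaryError(f"facet '{boundary.label}': boundary failed to close "
                            "into an edge cycle")

    # face adjacency graph with boundary-crossing links removed
    graph: dict[int, list[int]] = {}
    blocked_pairs: list[tuple[int, int]] = []
    for (f1, f2), (a, b) in zip(mesh.face_adjacency, mesh.face_adjacency_edges):
        if (min(int(a), int(b)), max(int(a), int(b))) in boundary_edges:
            blocked_pairs.append((int(f1), int(f2)))
            continue
        graph.setdefault(int(f1), []).append(int(f2))
        graph.setdefault(int(f2), []).append(int(f1))

    start = _seed_face(mesh, tree, boundary.seed)
    region = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for w in graph.get(u, ()):
            if w not in region:
                region.add(w)
                queue.append(w)
    # a leak means the fill wrapped around the cycle: both faces flanking
    # some boundary edge ended up inside the region
    for f1, f2 in blocked_pairs:
        if f1 in region and f2 in region:
            raise BoundaryError(
                f"facet '{boundary.label}': flood fill leaked around the "
                "boundary (both sides of a boundary edge were filled) — the "
                "snapped cycle does not close")
    area_mm2 = float(mesh.area_faces[sorted(region)].sum())
    return area_mm2 / _MM2_PER_CM2


# ---------------------------------------------------------------------------
# full measurement
# ---------------------------------------------------------------------------

def measure_all(landmarks: LandmarkSet,
                mesh: Optional[trimesh.Trimesh] = None,
                boundaries: Optional[Iterable[FacetBoundary]] = None,
                ) -> MorphometricRecord:
    """Measure the nine parameters from landmarks (and mesh + boundaries).

    The seven landmark parameters are always computed; APF and AMF require a
    surface mesh plus boundaries labelled "posterior" and "middle" and are
    ``None`` otherwise.
    """
    _, _, lca, hpf = axis_and_height(landmarks.A, landmarks.C, landmarks.D,
                                     landmarks.E)
    rec = dict(
        LCA=lca,
        HPF=hpf,
        LPF=distance(landmarks.A, landmarks.B),
        LAP=distance(landmarks.B, landmarks.C),
        HAP=distance(landmarks.C, landmarks.D),
        GA=gissane_angle(landmarks.A, landmarks.B, landmarks.C),
        BA=bohler_angle(landmarks.A, landmarks.C, landmarks.F),
    )
    areas: dict[str, Optional[float]] = {"APF": None, "AMF": None}
    if mesh is not None and boundaries is not None:
        for b in boundaries:
            key = "APF" if b.label == "posterior" else "AMF"
            areas[key] = facet_area(mesh, b)
    return MorphometricRecord(**rec, **areas)


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def write_landmarks(landmarks: LandmarkSet, path) -> None:
    """Write landmarks as CSV with columns name, x_mm, y_mm, z_mm."""
    rows = [{"name": n, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for n, p in landmarks.as_dict().items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark CSV (name, x_mm, y_mm, z_mm) into a LandmarkSet."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap as data error
        raise DataError(f"cannot parse landmark file {path}: {exc}") from exc
    required = {"name", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise DataError(f"landmark file {path} must have columns {sorted(required)}")
    pts = {}
    for _, row in df.iterrows():
        pts[str(row["name"]).strip()] = np.array(
            [row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)
    missing = [n for n in LANDMARK_NAMES if n not in pts]
    if missing:
        raise MissingLandmarkError(
            f"landmark file {path} is missing landmarks {missing}")
    return LandmarkSet(**{n: pts[n] for n in LANDMARK_NAMES})


def write_boundaries(boundaries: Sequence[FacetBoundary], path) -> None:
    """Write facet boundaries as CSV rows (facet, role, x_mm, y_mm, z_mm)."""
    rows = []
    for b in boundaries:
        for p in b.points:
            rows.append({"facet": b.label, "role": "boundary",
                         "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
        rows.append({"facet": b.label, "role": "seed",
                     "x_mm": b.seed[0], "y_mm": b.seed[1], "z_mm": b.seed[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_boundaries(path) -> list[FacetBoundary]:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse boundary file {path}: {exc}") from exc
    required = {"facet", "role", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise DataError(f"boundary file {path} must have columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("facet", sort=False):
        loop = grp[grp["role"] == "boundary"][["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        seeds = grp[grp["role"] == "seed"][["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        if len(seeds) != 1:
            raise DataError(f"facet '{label}' in {path} must have exactly one seed row")
        out.append(FacetBoundary(points=loop, seed=seeds[0], label=str(label)))
    return out
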