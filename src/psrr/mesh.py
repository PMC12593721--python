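"""Triangulated meshes for the SPDE fields.

The mesh domain is the nonconvex (concave) hull of the data points dilated by
a buffer, so the Gaussian field is estimated on an extension of the sampled
region and boundary effects stay away from the data.  Construction seeds the
triangulation with the data points, points along the extension boundary and a
quasi-regular interior lattice, then repeatedly splits any triangle edge
longer than ``max_edge_km`` at its midpoint and re-triangulates (Delaunay
refinement by midpoint insertion).

Barycentric interpolation from mesh vertices to arbitrary locations is
exposed as a sparse projector matrix whose rows are convex weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Polygon

from .spde import fem_matrices

__all__ = ["Mesh", "build_mesh"]

_MAX_REFINE_ITER = 40


@dataclass
class Mesh:
    """A refined triangulation with its domain polygons.

    ``triangles`` indexes only the triangles kept inside the extension
    boundary; ``interior_boundary`` is the concave hull of the data points
    and ``extension_boundary`` its dilation.
    """

    vertices: np.ndarray  # (n, 2) km
    triangles: np.ndarray  # (t, 3) vertex indices
    interior_boundary: Polygon
    extension_boundary: Polygon
    max_edge_km: float
    data_indices: np.ndarray  # indices of the original data points
    _delaunay: Delaunay = field(repr=False, default=None)
    _fem_cache: tuple = field(repr=False, default=None)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edge_lengths(self) -> np.ndarray:
        """Lengths of the unique edges of the kept triangles."""
        edges = set()
        for a, b, c in self.triangles:
            for i, j in ((a, b), (b, c), (c, a)):
                edges.add((min(i, j), max(i, j)))
        e = np.array(sorted(edges))
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def fem(self):
        """Cached lumped mass diagonal and stiffness matrix."""
        if self._fem_cache is None:
            self._fem_cache = fem_matrices(self.vertices, self.triangles)
        return self._fem_cache

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return shapely.contains_xy(
            self.extension_boundary.buffer(1e-9), pts[:, 0], pts[:, 1]
        )

    def projector(self, points: np.ndarray) -> sp.csr_matrix:
        """Sparse barycentric interpolation matrix to ``points``.

        Raises ``ValueError`` listing any point outside the mesh extension.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = self.contains(pts)
        simplex = self._delaunay.find_simplex(pts)
        bad = ~inside | (simplex < 0)
        if bad.any():
            offenders = pts[bad][:10].tolist()
            raise ValueError(f"locations outside mesh extension: {offenders}")
        trans = self._delaunay.transform[simplex]
        bary2 = np.einsum(
            "ijk,ik->ij", trans[:, :2, :], pts - trans[:, 2, :]
        )
        weights = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        # Clip tiny negative weights from points on triangle edges.
        weights = np.clip(weights, 0.0, None)
        weights /= weights.sum(axis=1, keepdims=True)
        cols = self._delaunay.simplices[simplex]
        rows = np.repeat(np.arange(len(pts)), 3)
        a = sp.csr_matrix(
            (weights.ravel(), (rows, cols.ravel())),
            shape=(len(pts), self.n_vertices),
        )
        return a


def _boundary_points(poly: Polygon, spacing: float) -> np.ndarray:
    ring = poly.exterior
    n = max(int(np.ceil(ring.length / spacing)), 8)
    dists = np.linspace(0.0, ring.length, n, endpoint=False)
    return np.array([ring.interpolate(d).coords[0] for d in dists])


def _interior_lattice(poly: Polygon, spacing: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    ys = np.arange(miny + dy / 2, maxy, dy)
    pts = []
    for k, y in enumerate(ys):
        offset = (k % 2) * spacing / 2.0
        xs = np.arange(minx + offset + spacing / 2, maxx, spacing)
        pts.extend((x, y) for x in xs)
    if not pts:
        return np.empty((0, 2))
    pts = np.array(pts)
    keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return pts[keep]


def build_mesh(
    points: np.ndarray,
    max_edge_km: float,
    hull_buffer_km: float | None = None,
    concave_ratio: float = 0.5,
) -> Mesh:
    """Build a Delaunay-refined mesh over the buffered concave hull of points.

    Parameters
    ----------
    points : (n, 2) array
        Data locations in km; every point becomes a mesh vertex.
    max_edge_km : float
        Upper bound on triangle edge length after refinement.
    hull_buffer_km : float, optional
        Dilation of the concave hull; defaults to ``max_edge_km``.
    concave_ratio : float
        Tightness of the concave hull (shapely's ``ratio``; 1 is convex).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct points")
    if max_edge_km <= 0:
        raise ValueError("max_edge_km must be positive")
    if hull_buffer_km is None:
        hull_buffer_km = max_edge_km
    hull = shapely.concave_hull(MultiPoint(pts), ratio=concave_ratio)
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise ValueError("degenerate (e.g. collinear) point set")
    extension = hull.buffer(hull_buffer_km, quad_segs=4).simplify(max_edge_km / 20.0)

    spacing = 0.75 * max_edge_km
    boundary = _boundary_points(extension, spacing)
    lattice = _interior_lattice(extension, spacing)
    if len(lattice) and len(boundary):
        # Keep the lattice clear of the boundary ring to avoid slivers.
        d, _ = cKDTree(boundary).query(lattice)
        lattice = lattice[d > 0.4 * spacing]
    cand = np.vstack([boundary, lattice]) if len(lattice) else boundary
    # Keep candidates clear of the data points so they stay exact vertices.
    tree = cKDTree(pts)
    d, _ = tree.query(cand)
    cand = cand[d > 0.35 * spacing]
    vertices = np.vstack([pts, cand])
    n_data = len(pts)

    kept_tris = None
    for _ in range(_MAX_REFINE_ITER):
        tri = Delaunay(vertices)
        centroids = vertices[tri.simplices].mean(axis=1)
        kept = shapely.contains_xy(
            extension.buffer(1e-9), centroids[:, 0], centroids[:, 1]
        )
        # Qhull can emit (near-)degenerate simplices from collinear boundary
        # samples; they would wreck the finite-element conditioning.
        p = vertices[tri.simplices]
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        areas = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
        kept &= areas > 1e-8 * max_edge_km**2
        kept_tris = tri.simplices[kept]
        # Split every too-long edge of a kept triangle with a Steiner point
        # pulled toward the adjacent triangle's centroid: a point exactly on
        # a convex-hull chord would be dropped as coplanar by Qhull (stalling
        # refinement), and a barely-displaced one would make a sliver
        # triangle whose stiffness entries explode.
        edge_centroid: dict[tuple[int, int], np.ndarray] = {}
        for t_idx, (a, b, c) in enumerate(kept_tris):
            cen = centroids[kept][t_idx]
            for i, j in ((a, b), (b, c), (c, a)):
                edge_centroid.setdefault((min(i, j), max(i, j)), cen)
        e = np.array(sorted(edge_centroid))
        lengths = np.linalg.norm(vertices[e[:, 0]] - vertices[e[:, 1]], axis=1)
        long = lengths > max_edge_km
        if not long.any():
            break
        vtree = cKDTree(vertices)
        new_pts = []
        for i, j in e[long]:
            mid = 0.5 * (vertices[i] + vertices[j])
            mid = mid + 0.3 * (edge_centroid[(i, j)] - mid)
            if vtree.query(mid)[0] > 0.05 * max_edge_km:
                new_pts.append(mid)
        if not new_pts:
            break  # only stubborn hull chords remain; dropped below
        vertices = np.vstack([vertices, new_pts])
    # Drop any residual triangle with an over-long edge (boundary slivers
    # bridging concavities that midpoint insertion cannot remove).
    side = vertices[kept_tris] - vertices[np.roll(kept_tris, 1, axis=1)]
    ok = (np.linalg.norm(side, axis=2) <= max_edge_km * (1 + 1e-9)).all(axis=1)
    kept_tris = kept_tris[ok]
    used = np.unique(kept_tris)
    if len(np.intersect1d(used, np.arange(n_data))) < n_data:
        raise RuntimeError("mesh refinement left a data point uncovered")
    remap = -np.ones(len(vertices), dtype=int)
    remap[used] = np.arange(len(used))
    final_vertices = vertices[used]
    final_tris = remap[kept_tris]
    return Mesh(
        vertices=final_vertices,
        triangles=final_tris,
        interior_boundary=hull,
        extension_boundary=extension,
        max_edge_km=max_edge_km,
        data_indices=remap[np.arange(n_data)],
        _delaunay=Delaunay(final_vertices),
    )
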