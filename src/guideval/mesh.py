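"""Triangle-mesh data model, STL I/O, and signed surface-distance comparison.

Meshes are :class:`trimesh.Trimesh` objects in millimetre coordinates. The
module adds what the validation pipeline needs on top of trimesh:

* load-time cleaning (duplicate-vertex merge, zero-area face removal),
* a fast closest-point-on-surface query (:class:`SurfaceQuery`) built on a
  k-d tree over triangle centroids with exact point-triangle distances,
* signed vertex-to-surface distance maps between two surface models, with
  the convention that a positive value means the query vertex lies *outside*
  the reference surface (a larger query model than the reference model).

The sign is taken from the angle-weighted pseudo-normal of the closest
surface primitive (face, edge or vertex), which is exact for watertight
meshes with outward orientation (Baerentzen & Aanaes, 2005).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "STLParseError",
    "read_stl",
    "write_stl",
    "clean_mesh",
    "SurfaceQuery",
    "DistanceMap",
    "SurfaceComparisonSummary",
    "signed_vertex_distances",
    "summarize",
]


class STLParseError(ValueError):
    """Raised for malformed or truncated STL files."""


def clean_mesh(mesh: trimesh.Trimesh, merge_tol: float = 1e-6) -> trimesh.Trimesh:
    """Merge near-duplicate vertices and drop degenerate (zero-area) faces."""
    out = mesh.copy()
    out.merge_vertices(digits_vertex=int(round(-np.log10(merge_tol))))
    areas = trimesh.triangles.area(out.triangles)
    out.update_faces(areas > 1e-12)
    out.remove_unreferenced_vertices()
    return out


def read_stl(path) -> trimesh.Trimesh:
    """Read a binary or ASCII STL file into a cleaned mesh.

    Binary files are validated against the 84-byte header + 50 bytes per
    triangle layout; a truncated file raises :class:`STLParseError` naming
    the byte offset where data ran out.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 15:
        raise STLParseError(f"{path}: file too short ({len(raw)} bytes) to be an STL")
    is_ascii = raw.lstrip()[:5].lower() == b"solid" and b"facet" in raw[:1024].lower()
    if not is_ascii:
        if len(raw) < 84:
            raise STLParseError(
                f"{path}: binary STL truncated in header at byte {len(raw)} (need 84)"
            )
        (n_tri,) = np.frombuffer(raw[80:84], dtype="<u4")
        expected = 84 + 50 * int(n_tri)
        if len(raw) < expected:
            raise STLParseError(
                f"{path}: binary STL declares {n_tri} triangles "
                f"({expected} bytes) but ends at byte {len(raw)}"
            )
    try:
        loaded = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh internal failure modes
        raise STLParseError(f"{path}: unparseable STL ({exc})") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise STLParseError(f"{path}: STL contains no triangles")
    return clean_mesh(loaded)


def write_stl(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh as binary STL."""
    mesh.export(path, file_type="stl")


# ---------------------------------------------------------------------------
# Exact point-triangle closest points (vectorized Eberly region algorithm)
# ---------------------------------------------------------------------------

def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on ``triangles[i]`` to ``points[i]``, both length N."""
    P = np.asarray(points, float)
    tri = np.asarray(triangles, float)
    B, E0, E1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    D = B - P
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    d = np.einsum("ij,ij->i", E0, D)
    e = np.einsum("ij,ij->i", E1, D)
    det = a * c - b * b
    s = b * e - c * d
    t = b * d - a * e

    S = np.empty_like(a)
    T = np.empty_like(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = s + t <= det
        r0 = inner & (s >= 0) & (t >= 0)  # face interior
        S[r0] = s[r0] / det[r0]
        T[r0] = t[r0] / det[r0]

        r3 = inner & (s < 0) & (t >= 0)  # edge E1 (s=0)
        S[r3] = 0.0
        T[r3] = np.clip(-e[r3] / c[r3], 0.0, 1.0)

        r5 = inner & (s >= 0) & (t < 0)  # edge E0 (t=0)
        T[r5] = 0.0
        S[r5] = np.clip(-d[r5] / a[r5], 0.0, 1.0)

        r4 = inner & (s < 0) & (t < 0)  # corner region
        use_e0 = r4 & (d < 0)
        T[use_e0] = 0.0
        S[use_e0] = np.clip(-d[use_e0] / a[use_e0], 0.0, 1.0)
        use_e1 = r4 & ~(d < 0)
        S[use_e1] = 0.0
        T[use_e1] = np.clip(-e[use_e1] / c[use_e1], 0.0, 1.0)

        outer = ~inner
        denom = a - 2.0 * b + c  # squared length of edge v1->v2

        r2 = outer & (s < 0)
        tmp = (c + e) - (b + d)
        on_diag = r2 & (tmp > 0)
        S[on_diag] = np.clip(tmp[on_diag] / denom[on_diag], 0.0, 1.0)
        T[on_diag] = 1.0 - S[on_diag]
        off = r2 & ~(tmp > 0)
        S[off] = 0.0
        T[off] = np.clip(-e[off] / c[off], 0.0, 1.0)

        r6 = outer & (s >= 0) & (t < 0)
        tmp = (a + d) - (b + e)
        on_diag = r6 & (tmp > 0)
        T[on_diag] = np.clip(tmp[on_diag] / denom[on_diag], 0.0, 1.0)
        S[on_diag] = 1.0 - T[on_diag]
        off = r6 & ~(tmp > 0)
        T[off] = 0.0
        S[off] = np.clip(-d[off] / a[off], 0.0, 1.0)

        r1 = outer & (s >= 0) & (t >= 0)  # diagonal edge
        numer = (c + e) - (b + d)
        S[r1] = np.clip(numer[r1] / denom[r1], 0.0, 1.0)
        T[r1] = 1.0 - S[r1]

    return B + S[:, None] * E0 + T[:, None] * E1


class SurfaceQuery:
    """Closest-point and signed-distance queries against one mesh surface.

    Candidate triangles come from the ``n_candidates`` nearest triangle
    centroids (cKDTree); the exact minimum over candidates is then taken.
    For meshes whose triangle size is commensurate with feature size (all
    meshes this pipeline produces) the candidate set contains the true
    nearest triangle.
    """

    def __init__(self, mesh: trimesh.Trimesh, n_candidates: int = 16):
        if len(mesh.faces) == 0:
            raise ValueError("cannot query an empty mesh")
        self.mesh = mesh
        self._tri = mesh.triangles.view(np.ndarray)
        self._tree = cKDTree(self._tri.mean(axis=1))
        self._k = min(n_candidates, len(mesh.faces))
        self._face_normals = mesh.face_normals.view(np.ndarray)
        self._vertex_normals = None
        self._edge_normals = None

    def closest(self, points: np.ndarray):
        """Return ``(closest_points, distances, face_ids)`` for (N, 3) points."""
        pts = np.atleast_2d(np.asarray(points, float))
        n = len(pts)
        _, cand = self._tree.query(pts, k=self._k)
        cand = np.atleast_2d(cand)
        flat = cand.reshape(-1)
        rep = np.repeat(pts, self._k, axis=0)
        cp = closest_point_on_triangles(rep, self._tri[flat]).reshape(n, self._k, 3)
        d2 = np.einsum("nkj,nkj->nk", cp - pts[:, None, :], cp - pts[:, None, :])
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        return cp[rows, best], np.sqrt(d2[rows, best]), cand[rows, best]

    # -- pseudo-normals ----------------------------------------------------
    def _build_pseudo_normals(self) -> None:
        m = self.mesh
        self._vertex_normals = trimesh.geometry.weighted_vertex_normals(
            len(m.vertices), m.faces, m.face_normals, m.face_angles
        )
        edge_norm: dict = {}
        for (fa, fb), (va, vb) in zip(m.face_adjacency, m.face_adjacency_edges):
            edge_norm[(min(va, vb), max(va, vb))] = (
                self._face_normals[fa] + self._face_normals[fb]
            )
        self._edge_normals = edge_norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distances; positive = outside (assumes outward orientation)."""
        pts = np.atleast_2d(np.asarray(points, float))
        cp, dist, fid = self.closest(pts)
        if self._vertex_normals is None:
            self._build_pseudo_normals()
        bary = trimesh.triangles.points_to_barycentric(self._tri[fid], cp)
        normals = self._face_normals[fid].copy()
        tol = 1e-9
        near_zero = bary < tol
        n_zero = near_zero.sum(axis=1)
        faces = self.mesh.faces.view(np.ndarray)
        # closest point on an edge or at a vertex: face normal is ambiguous
        for i in np.nonzero(n_zero > 0)[0]:
            verts = faces[fid[i]]
            if n_zero[i] >= 2:  # at a vertex
                v = verts[np.argmax(bary[i])]
                normals[i] = self._vertex_normals[v]
            else:  # on an edge
                keep = verts[~near_zero[i]]
                key = (min(keep), max(keep))
                normals[i] = self._edge_normals.get(key, normals[i])
        sign = np.where(np.einsum("ij,ij->i", pts - cp, normals) < 0, -1.0, 1.0)
        return sign * dist


# ---------------------------------------------------------------------------
# Distance maps
# ---------------------------------------------------------------------------

@dataclass
class DistanceMap:
    """Per-vertex signed distances of a query mesh to a reference surface.

    Positive values mean the query vertex lies outside the reference model
    (the query model is locally larger than the reference).
    """

    values: np.ndarray
    query_vertices: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float).ravel()
        self.query_vertices = np.asarray(self.query_vertices, float).reshape(-1, 3)
        if len(self.values) != len(self.query_vertices):
            raise ValueError("one distance per query vertex required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": np.arange(len(self.values)),
                "x": self.query_vertices[:, 0],
                "y": self.query_vertices[:, 1],
                "z": self.query_vertices[:, 2],
                "signed_distance_mm": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SurfaceComparisonSummary:
    """Mean +/- SD (sample SD, n-1) of a signed distance map, in mm."""

    mean: float
    sd: float
    n_vertices: int


def signed_vertex_distances(
    query: trimesh.Trimesh,
    reference: trimesh.Trimesh,
    max_vertices: int | None = None,
    seed: int = 0,
) -> DistanceMap:
    """Signed distance from every query-mesh vertex to the reference surface.

    The reference must be watertight, otherwise inside/outside is undefined.
    ``max_vertices`` optionally subsamples query vertices (seeded) to bound
    cost on dense marching-cubes meshes.
    """
    if not reference.is_watertight:
        raise ValueError("reference mesh must be watertight for signed distances")
    ref = reference
    if ref.volume < 0:  # inward winding: flip so normals point out of the material
        ref = ref.copy()
        ref.invert()
    verts = query.vertices.view(np.ndarray)
    if max_vertices is not None and len(verts) > max_vertices:
        rng = np.random.default_rng(seed)
        verts = verts[rng.choice(len(verts), size=max_vertices, replace=False)]
    values = SurfaceQuery(ref).signed_distance(verts)
    return DistanceMap(values=values, query_vertices=verts)


def summarize(dmap: DistanceMap, absolute: bool = False) -> SurfaceComparisonSummary:
    """Mean and sample SD of the (optionally absolute) signed distances."""
    vals = np.abs(dmap.values) if absolute else dmap.values
    if len(vals) == 0:
        raise ValueError("empty distance map")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return SurfaceComparisonSummary(mean=float(np.mean(vals)), sd=sd, n_vertices=len(vals))
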