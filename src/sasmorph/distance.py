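"""Acromion-to-humerus distance mapping and the two subacromial width measures.

For every vertex of the (resampled) acromion surface a ray is cast along the
outward vertex normal with a fixed length budget (50 mm by default); if it
intersects the humerus surface, the Euclidean origin-to-hit distance is
recorded at that vertex.  Two scalar summaries are derived:

* ``MRI_Hum10`` — the mean of the 10% smallest recorded distances, a robust
  stand-in for the minimum subacromial width over the inferior acromion.
* ``MRI_Lat`` — the minimum point-to-surface distance from the most lateral
  acromion vertex to the humerus, mimicking the width visible to ultrasound
  at the lateral acromial edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .surface import BoneSurface, compute_vertex_normals

__all__ = [
    "DistanceMap",
    "SASMeasures",
    "cast_distance_map",
    "sas_hum10",
    "sas_lat",
    "export_heatmap",
    "read_heatmap",
    "ray_cast_first_hit",
    "point_to_mesh_distance",
]

_EPS = 1e-12


class NoOverlapError(ValueError):
    """No acromion ray reached the humerus within the ray budget."""


@dataclass
class DistanceMap:
    """Per-vertex ray-cast distances (mm) on an acromion surface.

    ``distances[i]`` is the Euclidean length from acromion vertex ``i`` to
    the first humerus intersection along the outward normal, or NaN when the
    ray misses within ``max_ray_mm``.
    """

    surface: BoneSurface
    distances: np.ndarray
    max_ray_mm: float = 50.0
    target_id: str = "humerus"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if len(self.distances) != self.surface.n_vertices:
            raise ValueError("one distance per acromion vertex required")

    @property
    def finite(self) -> np.ndarray:
        return self.distances[np.isfinite(self.distances)]

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.distances).sum())


@dataclass(frozen=True)
class SASMeasures:
    """Summary subacromial width measures for one subject/mask pair."""

    mri_hum10: float
    mri_lat: float
    n_valid: int
    fraction: float = 0.10
    lateral_axis: str = "+x"
    lat_vertex: tuple[float, float, float] | None = None


def _ray_triangle_batch(
    origins: np.ndarray, directions: np.ndarray, tri: np.ndarray, max_dist: float
) -> np.ndarray:
    """Moller-Trumbore: min hit distance per ray over candidate triangles.

    origins/directions: (r, 3); tri: (m, 3, 3). Returns (r,) with NaN misses.
    Directions must be unit-length so the ray parameter t is in mm.
    """
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    # pvec: (r, m, 3) = d x e2
    pvec = np.cross(directions[:, None, :], e2[None, :, :])
    det = np.einsum("mk,rmk->rm", e1, pvec)
    inv_det = np.where(np.abs(det) > _EPS, 1.0 / np.where(det == 0, 1.0, det), np.nan)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rmk,rmk->rm", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rmk,rk->rm", qvec, directions) * inv_det
    t = np.einsum("rmk,mk->rm", qvec, e2) * inv_det
    tol = 1e-9
    valid = (
        np.isfinite(t)
        & (u >= -tol)
        & (v >= -tol)
        & (u + v <= 1.0 + tol)
        & (t > tol)
        & (t <= max_dist)
    )
    t = np.where(valid, t, np.inf)
    best = t.min(axis=1)
    return np.where(np.isfinite(best), best, np.nan)


def ray_cast_first_hit(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    max_dist: float,
    chunk_size: int = 192,
) -> np.ndarray:
    """First-hit distances for many rays against a triangle soup.

    Rays are processed in spatially sorted chunks; each chunk only tests
    triangles whose bounding box overlaps the chunk's swept bounding box,
    which keeps the all-pairs Moller-Trumbore kernel tractable at 10^4 rays
    against 10^4 triangles.
    """
    origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=float).reshape(-1, 3, 3)
    n = len(origins)
    out = np.full(n, np.nan)
    if n == 0 or len(triangles) == 0:
        return out

    tri_lo = triangles.min(axis=1)
    tri_hi = triangles.max(axis=1)

    order = np.lexsort((origins[:, 2], origins[:, 1], origins[:, 0]))
    for start in range(0, n, chunk_size):
        idx = order[start : start + chunk_size]
        o = origins[idx]
        d = directions[idx]
        ends = o + d * max_dist
        lo = np.minimum(o, ends).min(axis=0)
        hi = np.maximum(o, ends).max(axis=0)
        cand = np.flatnonzero(
            np.all(tri_hi >= lo[None, :], axis=1) & np.all(tri_lo <= hi[None, :], axis=1)
        )
        if len(cand) == 0:
            continue
        out[idx] = _ray_triangle_batch(o, d, triangles[cand], max_dist)
    return out


def cast_distance_map(
    acromion: BoneSurface,
    humerus: BoneSurface,
    max_ray_mm: float = 50.0,
    bidirectional: bool = False,
) -> DistanceMap:
    """Ray-cast every acromion vertex along its outward normal at the humerus.

    Only the humerus is intersection-tested (the acromion never occludes
    itself); the first hit within ``max_ray_mm`` defines the distance. With
    ``bidirectional=True`` the opposite direction is also tried and the
    smaller hit kept — useful for meshes with unreliable orientation.
    """
    if acromion.normals is None:
        raise ValueError("acromion surface has no vertex normals; "
                         "run compute_vertex_normals first")
    if humerus.faces.size == 0:
        raise ValueError("humerus mesh is empty")
    tri = humerus.triangles
    dist = ray_cast_first_hit(acromion.vertices, acromion.normals, tri, max_ray_mm)
    if bidirectional:
        back = ray_cast_first_hit(acromion.vertices, -acromion.normals, tri, max_ray_mm)
        dist = np.fmin(dist, back)
    return DistanceMap(surface=acromion, distances=dist, max_ray_mm=max_ray_mm)


def sas_hum10(dmap: DistanceMap, fraction: float = 0.10) -> float:
    """Mean of the ``fraction`` closest finite distances (default 10%).

    The count m = max(1, round(fraction * n_valid)) is taken over vertices
    with finite distances; ties at the cutoff are resolved in stable
    vertex-index order (the mean is unaffected by tie order among equal
    values).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    finite_idx = np.flatnonzero(np.isfinite(dmap.distances))
    n_valid = len(finite_idx)
    if n_valid == 0:
        raise NoOverlapError(
            f"no subacromial overlap within the {dmap.max_ray_mm} mm ray budget"
        )
    m = max(1, int(np.floor(fraction * n_valid + 0.5)))
    vals = dmap.distances[finite_idx]
    order = np.argsort(vals, kind="stable")
    return float(vals[order[:m]].mean())


def _point_triangle_distances(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Euclidean distance from one point to each triangle (m, 3, 3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    # barycentric projection onto each triangle's plane
    ab = b - a
    ac = c - a
    ap = p[None, :] - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < _EPS, np.nan, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = np.isfinite(v) & (v >= 0) & (w >= 0) & (v + w <= 1)
    proj = a + v[:, None] * ab + w[:, None] * ac
    d_plane = np.linalg.norm(p[None, :] - proj, axis=1)

    def seg_dist(s0, s1):
        sv = s1 - s0
        denom_ = np.einsum("ij,ij->i", sv, sv)
        t = np.einsum("ij,ij->i", p[None, :] - s0, sv) / np.where(
            denom_ < _EPS, 1.0, denom_
        )
        t = np.clip(np.where(denom_ < _EPS, 0.0, t), 0.0, 1.0)
        closest = s0 + t[:, None] * sv
        return np.linalg.norm(p[None, :] - closest, axis=1)

    d_edges = np.min(
        np.stack([seg_dist(a, b), seg_dist(b, c), seg_dist(c, a)]), axis=0
    )
    return np.where(inside, d_plane, d_edges)


def point_to_mesh_distance(point: np.ndarray, mesh: BoneSurface) -> float:
    """Minimum Euclidean point-to-triangle distance (not ray-restricted)."""
    if mesh.faces.size == 0:
        raise ValueError("mesh is empty")
    p = np.asarray(point, dtype=float).ravel()
    return float(_point_triangle_distances(p, mesh.triangles).min())


def _parse_axis(axis_code: str) -> tuple[int, float]:
    code = axis_code.strip().lower()
    sign = 1.0
    if code[0] in "+-":
        sign = 1.0 if code[0] == "+" else -1.0
        code = code[1:]
    try:
        ax = {"x": 0, "y": 1, "z": 2}[code]
    except KeyError:
        raise ValueError(f"unknown lateral axis code {axis_code!r}") from None
    return ax, sign


def sas_lat(
    acromion: BoneSurface, humerus: BoneSurface, lateral_axis: str = "+x"
) -> tuple[float, np.ndarray]:
    """Minimum distance from the most lateral acromion vertex to the humerus.

    The vertex with the extreme coordinate along ``lateral_axis`` (default +x
    in RAS, i.e. the patient's right — appropriate for a right shoulder) is
    selected, ties broken toward the smallest vertex index; the returned
    distance is the Euclidean point-to-surface minimum, not restricted to the
    normal direction.  Returns ``(distance_mm, lateral_vertex_xyz)``.
    """
    if acromion.vertices.size == 0 or humerus.faces.size == 0:
        raise ValueError("both meshes must be non-empty")
    ax, sign = _parse_axis(lateral_axis)
    coord = sign * acromion.vertices[:, ax]
    vidx = int(np.flatnonzero(coord == coord.max())[0])
    p = acromion.vertices[vidx]
    return point_to_mesh_distance(p, humerus), p.copy()


def export_heatmap(dmap: DistanceMap, path) -> None:
    """Write the acromion mesh with a per-vertex scalar array ``sas_mm``.

    ``.vtk`` writes legacy-ASCII VTK PolyData (POINT_DATA scalar ``sas_mm``);
    ``.ply`` writes PLY with a per-vertex ``sas_mm`` property.  Vertices whose
    ray missed carry NaN.
    """
    path = Path(path)
    if path.suffix == ".vtk":
        _write_vtk_polydata(path, dmap.surface, {"sas_mm": dmap.distances})
    elif path.suffix == ".ply":
        mesh = dmap.surface.as_trimesh()
        mesh.vertex_attributes["sas_mm"] = dmap.distances.astype(np.float64)
        mesh.export(str(path))
    else:
        raise ValueError(f"unsupported heatmap format {path.suffix!r} (use .vtk or .ply)")


def read_heatmap(path) -> tuple[BoneSurface, np.ndarray]:
    """Read a heatmap written by :func:`export_heatmap` (.vtk only)."""
    path = Path(path)
    if path.suffix != ".vtk":
        raise ValueError("read_heatmap supports the legacy .vtk format")
    return _read_vtk_polydata(path)


def _write_vtk_polydata(path: Path, surface: BoneSurface, scalars: dict) -> None:
    v = surface.vertices
    f = surface.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "sasmorph subacromial distance heatmap (NaN = no intersection)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    lines += [" ".join(f"{x:.10g}" for x in row) for row in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 " + " ".join(str(i) for i in row) for row in f]
    lines.append(f"POINT_DATA {len(v)}")
    for name, data in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{x:.10g}" if np.isfinite(x) else "nan" for x in data]
    path.write_text("\n".join(lines) + "\n")


def _read_vtk_polydata(path: Path) -> tuple[BoneSurface, np.ndarray]:
    tokens = path.read_text().split("\n")
    i = 0
    verts = faces = scal = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            verts = np.array(
                [[float(x) for x in tokens[i + 1 + j].split()] for j in range(n)]
            )
            i += n
        elif line.startswith("POLYGONS"):
            m = int(line.split()[1])
            faces = np.array(
                [[int(x) for x in tokens[i + 1 + j].split()[1:]] for j in range(m)]
            )
            i += m
        elif line.startswith("SCALARS"):
            n = len(verts)
            scal = np.array([float(tokens[i + 2 + j]) for j in range(n)])
            i += n + 1
        i += 1
    surf = BoneSurface(vertices=verts, faces=faces, provenance=[f"read:{path.name}"])
    return compute_vertex_normals(surf), scal


def compute_sas_measures(
    acromion: BoneSurface,
    humerus: BoneSurface,
    max_ray_mm: float = 50.0,
    fraction: float = 0.10,
    lateral_axis: str = "+x",
    bidirectional: bool = False,
) -> tuple[SASMeasures, DistanceMap]:
    """Convenience wrapper: distance map plus both summary measures."""
    dmap = cast_distance_map(acromion, humerus, max_ray_mm, bidirectional)
    hum10 = sas_hum10(dmap, fraction)
    lat, lat_vertex = sas_lat(acromion, humerus, lateral_axis)
    measures = SASMeasures(
        mri_hum10=hum10,
        mri_lat=lat,
        n_valid=dmap.n_valid,
        fraction=fraction,
        lateral_axis=lateral_axis,
        lat_vertex=tuple(lat_vertex),
    )
    return measures, dmap
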