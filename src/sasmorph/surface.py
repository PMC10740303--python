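"""Bone-mask post-processing: Gaussian smoothing, iso-surface extraction,
uniform resampling and vertex normals.

The processing chain mirrors how shoulder bone surfaces are typically built
from manual segmentations: the binary mask is blurred with a Gaussian whose
variance is specified in physical units (mm^2), an iso-surface is extracted
with marching cubes, the mesh is resampled to a uniform target vertex count
by Voronoi-style vertex clustering, and outward per-vertex normals are
attached so the subacromial distance map can be ray-cast from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from nibabel.affines import apply_affine
from scipy import ndimage
from skimage import measure
from scipy.spatial import cKDTree

__all__ = [
    "SegmentationMask",
    "ScalarField",
    "SmoothingParams",
    "BoneSurface",
    "read_mask",
    "write_mask",
    "smooth_mask",
    "extract_surface",
    "resample_surface",
    "compute_vertex_normals",
]


class MaskFormatError(ValueError):
    """Raised when a NIfTI payload cannot be interpreted as a 3D binary mask."""


class SurfaceExtractionError(ValueError):
    """Raised when no iso-surface can be extracted from a scalar field."""


@dataclass(frozen=True)
class SegmentationMask:
    """3D binary voxel grid with a world affine (RAS millimetres).

    ``voxels[i, j, k]`` is foreground iff the voxel belongs to the bone; the
    world position of a voxel centre is ``affine @ (i, j, k, 1)``.
    """

    voxels: np.ndarray
    affine: np.ndarray
    label: str = "bone"

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise MaskFormatError(
                f"mask must be 3D, got {self.voxels.ndim}D payload"
            )
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise MaskFormatError("mask affine is not invertible")
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=bool))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3]

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return apply_affine(np.linalg.inv(self.affine), np.asarray(xyz, dtype=float))

    @classmethod
    def from_spacing(
        cls,
        voxels: np.ndarray,
        spacing,
        origin=(0.0, 0.0, 0.0),
        label: str = "bone",
    ) -> "SegmentationMask":
        affine = np.eye(4)
        affine[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
        affine[:3, 3] = np.asarray(origin, dtype=float)
        return cls(voxels=voxels, affine=affine, label=label)


@dataclass(frozen=True)
class ScalarField:
    """Smoothed occupancy field on the same grid as its source mask."""

    values: np.ndarray
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian smoothing configuration.

    ``variance_mm2`` is the filter variance sigma^2 in mm^2 (so the kernel
    standard deviation is ``sqrt(variance_mm2)`` mm, applied isotropically in
    physical space and therefore anisotropically in voxel units on
    anisotropic grids). ``iso_level`` is the marching-cubes threshold on the
    blurred occupancy in (0, 1); 0.5 is the midpoint of a blurred binary edge.
    """

    variance_mm2: float = 1.56
    iso_level: float = 0.5

    def __post_init__(self) -> None:
        if self.variance_mm2 <= 0:
            raise ValueError(f"variance_mm2 must be > 0, got {self.variance_mm2}")
        if not 0.0 < self.iso_level < 1.0:
            raise ValueError(f"iso_level must lie in (0, 1), got {self.iso_level}")

    @property
    def sigma_mm(self) -> float:
        return float(np.sqrt(self.variance_mm2))


@dataclass
class BoneSurface:
    """Triangle mesh in world (mm) coordinates with per-vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces index out-of-range vertices")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) triangle vertex coordinates."""
        return self.vertices[self.faces]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    def transformed(self, matrix: np.ndarray) -> "BoneSurface":
        """Apply a 4x4 rigid/affine transform; normals get the rotation part."""
        matrix = np.asarray(matrix, dtype=float)
        verts = apply_affine(matrix, self.vertices)
        normals = None
        if self.normals is not None:
            rot = matrix[:3, :3]
            normals = self.normals @ rot.T
            normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return BoneSurface(
            vertices=verts,
            faces=self.faces.copy(),
            normals=normals,
            provenance=self.provenance + ["transformed"],
        )

    def export(self, path) -> None:
        """Write the mesh as PLY (or any format trimesh supports by suffix)."""
        self.as_trimesh().export(str(path))


def read_mask(path, label_value: float | None = None, label: str = "bone") -> SegmentationMask:
    """Load a 3D binary mask from NIfTI.

    Non-binary payloads are binarized against ``label_value`` if given,
    otherwise against "> 0".  Spacing/origin come from the NIfTI affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise MaskFormatError(
            f"expected a 3D mask, got shape {data.shape} in {path.name}"
        )
    if label_value is not None:
        voxels = data == label_value
    else:
        voxels = data > 0
    return SegmentationMask(voxels=voxels, affine=np.asarray(img.affine), label=label)


def write_mask(mask: SegmentationMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def smooth_mask(mask: SegmentationMask, params: SmoothingParams | None = None) -> ScalarField:
    """Gaussian-blur a binary mask into a [0, 1] occupancy field.

    The kernel is isotropic in millimetres: per-axis sigma in voxel units is
    ``sqrt(variance_mm2) / spacing_axis``.
    """
    params = params or SmoothingParams()
    if mask.n_foreground == 0:
        raise ValueError("cannot smooth an empty mask (no foreground voxels)")
    sigma_vox = params.sigma_mm / mask.spacing
    values = ndimage.gaussian_filter(
        mask.voxels.astype(float), sigma=sigma_vox, mode="constant", cval=0.0
    )
    np.clip(values, 0.0, 1.0, out=values)
    return ScalarField(values=values, affine=mask.affine)


def _largest_component(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    parts = mesh.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    areas = [p.area for p in parts]
    return parts[int(np.argmax(areas))]


def _orient_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    trimesh.repair.fix_normals(mesh)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def extract_surface(
    f: ScalarField, iso_level: float = 0.5, keep_largest: bool = True
) -> BoneSurface:
    """Marching-cubes iso-surface of a smoothed occupancy field, in world mm.

    The largest connected component is retained (each mask holds one bone;
    smaller fragments are marching-cubes speckle) and the winding is fixed so
    normals point outward on closed surfaces.
    """
    vmin, vmax = float(f.values.min()), float(f.values.max())
    if not vmin < iso_level < vmax:
        raise SurfaceExtractionError(
            f"iso-level {iso_level} outside field range [{vmin:.3g}, {vmax:.3g}]"
        )
    verts_ijk, faces, _, _ = measure.marching_cubes(f.values, level=iso_level)
    verts = apply_affine(np.asarray(f.affine, dtype=float), verts_ijk)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if keep_largest:
        mesh = _largest_component(mesh)
    mesh = _orient_outward(mesh)
    surf = BoneSurface(
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        provenance=[f"marching_cubes(level={iso_level})"],
    )
    return compute_vertex_normals(surf)


def compute_vertex_normals(surface: BoneSurface) -> BoneSurface:
    """Attach area-weighted per-vertex unit normals.

    Each face's (un-normalized) cross product — whose magnitude is twice the
    face area — is accumulated onto its three vertices, so large faces
    dominate their vertices' normals. Vertices whose accumulated normal is
    degenerate (zero-area neighbourhood) are reported in the provenance log
    and given an arbitrary unit vector.
    """
    tri = surface.triangles
    face_cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    acc = np.zeros_like(surface.vertices)
    for c in range(3):
        np.add.at(acc, surface.faces[:, c], face_cross)
    norms = np.linalg.norm(acc, axis=1)
    degenerate = norms < 1e-12
    acc[degenerate] = (1.0, 0.0, 0.0)
    norms[degenerate] = 1.0
    normals = acc / norms[:, None]
    prov = list(surface.provenance)
    if degenerate.any():
        prov.append(f"degenerate_normal_vertices={np.flatnonzero(degenerate).tolist()}")
    return BoneSurface(
        vertices=surface.vertices, faces=surface.faces, normals=normals, provenance=prov
    )


def _lloyd_cluster(
    verts: np.ndarray, k: int, seed: int, n_iter: int = 15
) -> np.ndarray:
    """Partition vertices into k compact clusters by Lloyd iteration.

    Centres start at a seeded random vertex subset (near-uniform on a
    uniformly triangulated surface) and relax toward the centroidal-Voronoi
    configuration; nearest-centre assignment runs through a KD-tree so the
    cost stays ~O(n log k) per sweep even at k ~ 10^4.
    """
    rng = np.random.default_rng(seed)
    centers = verts[rng.choice(len(verts), size=k, replace=False)]
    labels = np.zeros(len(verts), dtype=np.int64)
    for _ in range(n_iter):
        _, labels = cKDTree(centers).query(verts, k=1)
        counts = np.bincount(labels, minlength=k).astype(float)
        new = np.zeros_like(centers)
        for c in range(3):
            new[:, c] = np.bincount(labels, weights=verts[:, c], minlength=k)
        nonempty = counts > 0
        new[nonempty] /= counts[nonempty, None]
        new[~nonempty] = centers[~nonempty]  # keep stale centres; harmless
        if np.allclose(new, centers, atol=1e-9):
            centers = new
            break
        centers = new
    _, labels = cKDTree(centers).query(verts, k=1)
    return labels


def resample_surface(
    surface: BoneSurface,
    n_target: int = 10_000,
    seed: int = 0,
    max_subdivisions: int = 3,
) -> BoneSurface:
    """Resample a mesh to ~``n_target`` uniformly distributed vertices.

    Vertices are partitioned into ``n_target`` compact clusters by k-means in
    3D (an approximation of centroidal-Voronoi clustering: clusters have
    near-uniform size on a uniformly triangulated surface). Each cluster
    contributes one output vertex at its centroid, and input faces spanning
    three distinct clusters become output faces, preserving orientation.

    If the input has fewer vertices than ``n_target`` it is Loop-subdivided
    up to ``max_subdivisions`` times first; if that budget is insufficient a
    ValueError is raised.
    """
    if n_target < 4:
        raise ValueError(f"n_target must be >= 4, got {n_target}")
    if surface.n_vertices < 4:
        raise ValueError("input mesh must have >= 4 vertices")

    # oversample so every cluster holds several vertices; clusters of ~1
    # vertex go empty during refinement and erode the output count
    mesh = surface.as_trimesh()
    subdiv = 0
    while len(mesh.vertices) < 3 * n_target and subdiv < max_subdivisions:
        mesh = mesh.subdivide()
        subdiv += 1
    if len(mesh.vertices) < n_target:
        raise ValueError(
            f"n_target={n_target} exceeds vertex count {len(mesh.vertices)} "
            f"after {max_subdivisions} subdivisions"
        )

    dense = compute_vertex_normals(
        BoneSurface(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))
    )
    verts = dense.vertices
    faces = dense.faces
    labels = _lloyd_cluster(verts, n_target, seed)

    # one representative vertex per non-empty cluster: the mean of its members
    centroids = np.zeros((n_target, 3))
    counts = np.bincount(labels, minlength=n_target).astype(float)
    for c in range(3):
        centroids[:, c] = np.bincount(labels, weights=verts[:, c], minlength=n_target)
    nonempty = counts > 0
    centroids[nonempty] /= counts[nonempty, None]

    face_labels = labels[faces]
    distinct = (
        (face_labels[:, 0] != face_labels[:, 1])
        & (face_labels[:, 1] != face_labels[:, 2])
        & (face_labels[:, 0] != face_labels[:, 2])
    )
    new_faces = face_labels[distinct]
    # deduplicate faces that collapse to the same cluster triple, keeping the
    # first occurrence's winding
    key = np.sort(new_faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    new_faces = new_faces[np.sort(first)]

    used = np.zeros(n_target, dtype=bool)
    used[new_faces.ravel()] = True
    remap = -np.ones(n_target, dtype=np.int64)
    remap[used] = np.arange(used.sum())
    out = trimesh.Trimesh(
        vertices=centroids[used], faces=remap[new_faces], process=False
    )
    out.update_faces(out.nondegenerate_faces())
    out = _orient_outward(out)

    # normals: area-weighted cluster average of the source mesh's outward
    # normals — collapsed face pairs can carry arbitrary winding, so normals
    # recomputed from the decimated faces would flip at isolated vertices
    acc = np.zeros((n_target, 3))
    for c in range(3):
        acc[:, c] = np.bincount(labels, weights=dense.normals[:, c], minlength=n_target)
    norms = np.linalg.norm(acc, axis=1)
    bad = norms < 1e-12
    acc[bad] = (1.0, 0.0, 0.0)
    norms[bad] = 1.0
    normals = (acc / norms[:, None])[used]

    return BoneSurface(
        vertices=np.asarray(out.vertices),
        faces=np.asarray(out.faces),
        normals=normals,
        provenance=surface.provenance
        + [f"voronoi_cluster_resample(n_target={n_target}, seed={seed}, subdiv={subdiv})"],
    )
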