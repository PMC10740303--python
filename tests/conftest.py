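import numpy as np
import pytest
import trimesh

import sasmorph as sm
from sasmorph.surface import BoneSurface, compute_vertex_normals


def make_surface(mesh: trimesh.Trimesh) -> BoneSurface:
    """Wrap a trimesh as a BoneSurface with outward area-weighted normals."""
    surf = BoneSurface(
        vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces)
    )
    return compute_vertex_normals(surf)


def plate_mesh(center, extents, subdivisions: int = 3) -> BoneSurface:
    """Axis-aligned box, subdivided so face-interior vertices exist whose
    area-weighted normals equal the exact face normal."""
    box = trimesh.creation.box(extents=extents)
    for _ in range(subdivisions):
        box = box.subdivide()
    box.apply_translation(center)
    return make_surface(box)


def down_facing(surf: BoneSurface) -> "np.ndarray":
    """Vertices whose outward normal points straight down (-z)."""
    return surf.normals[:, 2] < -0.999


@pytest.fixture(scope="session")
def sphere_mask():
    """Voxelized r=20 mm sphere at 0.8 mm isotropic spacing, world-centred."""
    r, sp = 20.0, 0.8
    n = int(2 * (r + 6 * sp) / sp) | 1
    origin = -(n - 1) * sp / 2.0
    g = origin + sp * np.arange(n)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    vox = xx**2 + yy**2 + zz**2 <= r**2
    return sm.SegmentationMask.from_spacing(vox, (sp, sp, sp), (origin,) * 3), r


@pytest.fixture(scope="session")
def sphere_surface(sphere_mask):
    mask, r = sphere_mask
    f = sm.smooth_mask(mask, sm.SmoothingParams())
    return sm.extract_surface(f), r


@pytest.fixture(scope="session")
def standard_phantom():
    """Sphere+plate phantom at the 0.8 x 0.8 x 1 mm protocol spacing."""
    spec = sm.PhantomSpec(gap_mm=9.5)
    humerus, acromion, true_gap = sm.generate_phantom(spec)
    return spec, humerus, acromion, true_gap


@pytest.fixture(scope="session")
def standard_phantom_run(standard_phantom):
    """Full pipeline result on the standard phantom (shared: ~5 s)."""
    spec, humerus, acromion, true_gap = standard_phantom
    measures, dmap, log = sm.masks_to_measures(humerus, acromion)
    return spec, true_gap, measures, dmap, log
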