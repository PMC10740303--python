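"""Synthetic shoulder phantoms and simulated rater measurement tables.

Real subacromial-width studies start from manually segmented MRI masks and
repeated sonographer measurements, neither of which ships with this package.
Two generators stand in for them:

* a voxelized **geometric phantom** — a sphere for the humeral head and a
  (optionally tilted) rectangular plate for the acromial shelf — whose
  minimum inter-bone distance is known in closed form, so the surface and
  distance stages can be validated against ground truth;
* a **two-way random-effects simulator** for subject x rater x repetition
  width tables, the exact additive Gaussian model under which ICC(2,1) is
  defined, with controllable subject, rater and error variance components
  and a closed-form implied population ICC.

Default simulation conditions mirror a typical healthy-adult cohort:
18 subjects, 2 raters, 3 repetitions, widths near 11-13 mm with a
between-subject SD of ~2 mm and a ~1.3 mm systematic novice-expert offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .surface import SegmentationMask, write_mask

__all__ = [
    "PhantomSpec",
    "RaterSimSpec",
    "generate_phantom",
    "simulate_measurements",
    "write_measurements",
    "read_measurements",
]

MEASUREMENT_COLUMNS = ("subject_id", "rater", "position", "repetition", "sas_mm")


@dataclass(frozen=True)
class PhantomSpec:
    """Sphere-plus-plate shoulder phantom with an analytically known gap.

    The humeral head is a sphere of ``humeral_radius`` centred at the world
    origin; the acromial shelf is a plate of lateral x anteroposterior extent
    ``shelf_extent`` and thickness ``shelf_thickness`` whose lower face sits
    ``gap_mm`` above the sphere apex, optionally tilted about the
    anteroposterior (y) axis.  With zero tilt the minimum solid-to-solid
    distance equals ``gap_mm`` exactly, realized directly above the apex.
    Axes are RAS: +x lateral (right shoulder), +z superior.
    """

    humeral_radius: float = 20.0
    gap_mm: float = 9.5
    shelf_thickness: float = 8.0
    shelf_extent: float = 30.0
    shelf_tilt_deg: float = 0.0
    voxel_spacing: tuple[float, float, float] = (0.8, 0.8, 1.0)
    grid_shape: tuple[int, int, int] | None = None
    margin_voxels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_mm <= 0:
            raise ValueError(f"gap_mm must be > 0, got {self.gap_mm}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be > 0, got {self.voxel_spacing}")
        if self.humeral_radius <= 0 or self.shelf_thickness <= 0 or self.shelf_extent <= 0:
            raise ValueError("phantom dimensions must be positive")

    # --- closed-form geometry -------------------------------------------------
    @property
    def plate_center(self) -> np.ndarray:
        z0 = self.humeral_radius + self.gap_mm
        return np.array([0.0, 0.0, z0 + self.shelf_thickness / 2.0])

    @property
    def plate_half_extents(self) -> np.ndarray:
        return np.array(
            [self.shelf_extent / 2.0, self.shelf_extent / 2.0, self.shelf_thickness / 2.0]
        )

    @property
    def plate_rotation(self) -> np.ndarray:
        """Rotation matrix of the plate about the y axis (box -> world)."""
        t = np.deg2rad(self.shelf_tilt_deg)
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    def analytic_gap(self) -> float:
        """Exact minimum distance between sphere and (possibly tilted) plate.

        Point-to-oriented-box distance of the sphere centre, minus the
        radius.  For zero tilt this is ``gap_mm`` by construction.
        """
        center_local = self.plate_rotation.T @ (-self.plate_center)
        clamped = np.clip(center_local, -self.plate_half_extents, self.plate_half_extents)
        return float(np.linalg.norm(center_local - clamped) - self.humeral_radius)


def _auto_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """World bounds covering both solids plus the voxel margin; returns
    (origin_mm, shape)."""
    r = spec.humeral_radius
    # conservative plate bounds: rotated box corners
    corners = np.array(
        [
            [sx, sy, sz]
            for sx in (-1, 1)
            for sy in (-1, 1)
            for sz in (-1, 1)
        ]
    ) * spec.plate_half_extents
    world_corners = (spec.plate_rotation @ corners.T).T + spec.plate_center
    lo = np.minimum(world_corners.min(axis=0), [-r, -r, -r])
    hi = np.maximum(world_corners.max(axis=0), [r, r, r])
    spacing = np.asarray(spec.voxel_spacing)
    pad = (spec.margin_voxels + 0.5) * spacing
    origin = lo - pad
    shape = np.ceil((hi + pad - origin) / spacing).astype(int) + 1
    return origin, shape


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[SegmentationMask, SegmentationMask, float]:
    """Voxelize the sphere + plate phantom onto a shared grid.

    A voxel is foreground iff its centre lies inside the solid, which is
    unbiased under grid refinement.  Returns ``(humerus, acromion,
    true_gap)`` where ``true_gap`` is the analytic minimum distance between
    the two solids.

    Raises a ValueError if the solids overlap or if either one comes closer
    than ``margin_voxels`` voxels to the grid boundary.
    """
    true_gap = spec.analytic_gap()
    if true_gap <= 0:
        raise ValueError(
            f"phantom solids overlap: analytic gap {true_gap:.3f} mm <= 0 "
            f"(gap_mm={spec.gap_mm}, tilt={spec.shelf_tilt_deg} deg)"
        )
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    if spec.grid_shape is None:
        origin, shape = _auto_grid(spec)
    else:
        shape = np.asarray(spec.grid_shape, dtype=int)
        origin = -(shape - 1) * spacing / 2.0  # grid centred on the sphere

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    centers = np.stack(
        [origin[a] + spacing[a] * g for a, g in enumerate((ii, jj, kk))], axis=-1
    )

    sphere = np.einsum("...k,...k->...", centers, centers) <= spec.humeral_radius**2

    local = np.einsum(
        "ab,...b->...a", spec.plate_rotation.T, centers - spec.plate_center
    )
    half = spec.plate_half_extents
    plate = np.all(np.abs(local) <= half, axis=-1)

    if (sphere & plate).any():
        raise ValueError("voxelized solids overlap on the shared grid")
    for name, vox in (("humerus", sphere), ("acromion", plate)):
        idx = np.argwhere(vox)
        if len(idx) == 0:
            raise ValueError(f"{name} produced no foreground voxels on this grid")
        lo_m = idx.min(axis=0)
        hi_m = shape - 1 - idx.max(axis=0)
        if (lo_m < spec.margin_voxels).any() or (hi_m < spec.margin_voxels).any():
            raise ValueError(
                f"{name} violates the {spec.margin_voxels}-voxel grid margin "
                f"(closest approach {int(min(lo_m.min(), hi_m.min()))} voxels); "
                "enlarge grid_shape or leave it automatic"
            )

    humerus = SegmentationMask.from_spacing(sphere, spacing, origin, label="humerus")
    acromion = SegmentationMask.from_spacing(plate, spacing, origin, label="acromion")
    return humerus, acromion, true_gap


@dataclass(frozen=True)
class RaterSimSpec:
    """Additive two-way random-effects model for repeated width measurements.

    value[s, r, t] = subject_true[s] + rater_bias[r] + rater_effect[r]
                     + interaction[s, r] + noise[s, r, t]

    with subject_true ~ N(subject_mean, subject_sd^2), rater_effect ~
    N(0, rater_effect_sd^2) redrawn per table, interaction ~ N(0, rater_sd^2)
    and noise ~ N(0, error_sd^2).  ``rater_bias`` are fixed per-rater offsets
    (e.g. a systematic novice overestimate).

    After averaging the ``n_reps`` repetitions, the implied population
    ICC(2,1) of the subject x rater table is

        subject_sd^2 / (subject_sd^2 + var(rater_bias) + rater_effect_sd^2
                        + rater_sd^2 + error_sd^2 / n_reps)

    where var(rater_bias) is the population variance of the fixed offsets.
    """

    n_subjects: int = 18
    k_raters: int = 2
    n_reps: int = 3
    subject_mean: float = 11.4
    subject_sd: float = 2.0
    rater_bias: tuple[float, ...] = (1.3, 0.0)
    rater_sd: float = 0.0
    rater_effect_sd: float = 0.0
    error_sd: float = 0.7
    position: str = "seated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.k_raters < 2 or self.n_reps < 1:
            raise ValueError("need n_subjects >= 2, k_raters >= 2, n_reps >= 1")
        if min(self.subject_sd, self.rater_sd, self.error_sd, self.rater_effect_sd) < 0:
            raise ValueError("all SDs must be >= 0")
        if len(self.rater_bias) != self.k_raters:
            raise ValueError(
                f"rater_bias must have one offset per rater "
                f"({self.k_raters}), got {len(self.rater_bias)}"
            )

    @property
    def implied_icc(self) -> float:
        bias = np.asarray(self.rater_bias, dtype=float)
        var_bias = float(np.mean((bias - bias.mean()) ** 2))
        s2 = self.subject_sd**2
        denom = (
            s2
            + var_bias
            + self.rater_effect_sd**2
            + self.rater_sd**2
            + self.error_sd**2 / self.n_reps
        )
        return s2 / denom if denom > 0 else 1.0

    @classmethod
    def for_population_icc(
        cls, icc: float, n_subjects: int = 18, k_raters: int = 2, seed: int = 0
    ) -> "RaterSimSpec":
        """Spec with unit error variance whose implied ICC equals ``icc``."""
        if not 0 < icc < 1:
            raise ValueError("target ICC must lie in (0, 1)")
        return cls(
            n_subjects=n_subjects,
            k_raters=k_raters,
            n_reps=1,
            subject_mean=11.4,
            subject_sd=float(np.sqrt(icc / (1 - icc))),
            rater_bias=(0.0,) * k_raters,
            rater_sd=0.0,
            rater_effect_sd=0.0,
            error_sd=1.0,
            seed=seed,
        )


def simulate_measurements(spec: RaterSimSpec) -> tuple[pd.DataFrame, float]:
    """Draw one long-format measurement table from the two-way model.

    Returns ``(table, implied_icc)``; the table has columns
    subject_id, rater, position, repetition, sas_mm and is reproducible for
    a fixed spec (all randomness flows from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    n, k, m = spec.n_subjects, spec.k_raters, spec.n_reps
    subject_true = rng.normal(spec.subject_mean, spec.subject_sd, size=n)
    rater_effect = rng.normal(0.0, spec.rater_effect_sd, size=k)
    interaction = rng.normal(0.0, spec.rater_sd, size=(n, k))
    noise = rng.normal(0.0, spec.error_sd, size=(n, k, m))
    values = (
        subject_true[:, None, None]
        + np.asarray(spec.rater_bias)[None, :, None]
        + rater_effect[None, :, None]
        + interaction[:, :, None]
        + noise
    )
    subj_ids = [f"S{i + 1:03d}" for i in range(n)]
    raters = [f"R{j + 1}" for j in range(k)]
    rows = [
        (subj_ids[i], raters[j], spec.position, t + 1, values[i, j, t])
        for i in range(n)
        for j in range(k)
        for t in range(m)
    ]
    table = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    table.attrs["implied_icc"] = spec.implied_icc
    table.attrs["seed"] = spec.seed
    return table, spec.implied_icc


def write_measurements(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement CSV {path.name} lacks columns {missing}")
    return table
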