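"""End-to-end orchestration: masks -> width measures, tables -> agreement.

``run_sas`` chains mask loading, Gaussian smoothing, marching cubes,
Voronoi-cluster resampling, normal computation, the 50 mm ray cast, and the
two summary measures; ``run_agreement`` turns a long-format measurement
table and a list of comparisons into a tidy agreement report (ICC with CI
and power, Bland–Altman, calibration regression) per comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as ag
from .distance import compute_sas_measures, export_heatmap, SASMeasures
from .phantom import read_measurements
from .surface import (
    SegmentationMask,
    SmoothingParams,
    extract_surface,
    read_mask,
    resample_surface,
    smooth_mask,
)

__all__ = ["PipelineConfig", "run_sas", "run_agreement", "masks_to_measures"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline constants, serialized with every run.

    Defaults follow the standard processing recipe: smoothing variance
    1.56 mm^2, iso-level 0.5, 10,000-point resampling, 50 mm ray budget,
    10% closest-point fraction, +x lateral axis (right shoulder), alpha
    0.05 and 1.96-SD limits of agreement.
    """

    variance_mm2: float = 1.56
    iso_level: float = 0.5
    n_resample: int = 10_000
    max_ray_mm: float = 50.0
    hum10_fraction: float = 0.10
    lateral_axis: str = "+x"
    bidirectional_rays: bool = False
    alpha: float = 0.05
    loa_multiplier: float = 1.96
    power_se_method: str = "n_minus_1"
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def masks_to_measures(
    humerus: SegmentationMask,
    acromion: SegmentationMask,
    config: PipelineConfig | None = None,
):
    """Library entry point: two co-registered masks -> (measures, dmap, log)."""
    config = config or PipelineConfig()
    if not np.allclose(humerus.affine, acromion.affine) or (
        humerus.voxels.shape != acromion.voxels.shape
    ):
        raise ValueError(
            "humerus and acromion masks are not co-registered "
            "(affine or grid shape mismatch)"
        )
    params = SmoothingParams(variance_mm2=config.variance_mm2, iso_level=config.iso_level)
    log: dict = {"config": dataclasses.asdict(config)}
    t0 = time.perf_counter()
    meshes = {}
    for name, mask in (("humerus", humerus), ("acromion", acromion)):
        f = smooth_mask(mask, params)
        surf = extract_surface(f, iso_level=config.iso_level)
        log[f"{name}_raw_vertices"] = surf.n_vertices
        surf = resample_surface(surf, n_target=config.n_resample, seed=config.seed)
        log[f"{name}_vertices"] = surf.n_vertices
        meshes[name] = surf
    measures, dmap = compute_sas_measures(
        meshes["acromion"],
        meshes["humerus"],
        max_ray_mm=config.max_ray_mm,
        fraction=config.hum10_fraction,
        lateral_axis=config.lateral_axis,
        bidirectional=config.bidirectional_rays,
    )
    log["n_valid"] = measures.n_valid
    log["elapsed_s"] = round(time.perf_counter() - t0, 3)
    if measures.n_valid < 0.05 * meshes["acromion"].n_vertices:
        log["warning"] = (
            f"only {measures.n_valid} of {meshes['acromion'].n_vertices} acromion "
            "vertices reached the humerus within the ray budget"
        )
    return measures, dmap, log


def run_sas(
    config: PipelineConfig,
    humerus_mask_path,
    acromion_mask_path,
    out_dir,
    subject_id: str = "subject",
) -> SASMeasures:
    """File-level pipeline run: NIfTI masks in, CSV + heatmap + log out.

    Deterministic for fixed config and inputs; outputs are ``measures.csv``
    (appended per subject), ``heatmap_<subject>.vtk`` and ``run_<subject>.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    humerus = read_mask(humerus_mask_path, label="humerus")
    acromion = read_mask(acromion_mask_path, label="acromion")
    measures, dmap, log = masks_to_measures(humerus, acromion, config)

    row = pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "mri_hum10_mm": measures.mri_hum10,
                "mri_lat_mm": measures.mri_lat,
                "n_valid": measures.n_valid,
            }
        ]
    )
    csv_path = out_dir / "measures.csv"
    row.to_csv(csv_path, mode="a", header=not csv_path.exists(), index=False)
    export_heatmap(dmap, out_dir / f"heatmap_{subject_id}.vtk")
    log["subject_id"] = subject_id
    log["inputs"] = [str(humerus_mask_path), str(acromion_mask_path)]
    (out_dir / f"run_{subject_id}.json").write_text(json.dumps(log, indent=2))
    return measures


def _select_series(
    averaged: pd.DataFrame, selector: dict, value_col: str = "sas_mm"
) -> pd.Series:
    sub = averaged
    for col, val in selector.items():
        if col not in sub.columns:
            raise ValueError(f"comparison selector references unknown column {col!r}")
        if val not in set(sub[col]):
            raise ValueError(f"no rows with {col} == {val!r} in measurement table")
        sub = sub[sub[col] == val]
    return sub.set_index("subject_id")[value_col]


def run_agreement(
    config: PipelineConfig,
    measurements,
    comparisons: list[dict],
    out_path=None,
) -> pd.DataFrame:
    """Agreement battery over a long-format measurement table.

    ``comparisons`` is a list of ``{"name": ..., "a": {selector}, "b":
    {selector}}`` where each selector fixes e.g. rater and position;
    repetitions are averaged first, differences and regressions are oriented
    a - b and y=b on x=a respectively (put the reference method in ``b``).
    One tidy row per comparison: ICC + CI + power + classification,
    Bland–Altman bias and limits, regression slope/intercept/R^2/RMSE/p.
    No multiple-testing correction is applied across comparisons.
    """
    if isinstance(measurements, (str, Path)):
        measurements = read_measurements(measurements)
    if (measurements["sas_mm"] <= 0).any() or not np.isfinite(
        measurements["sas_mm"]
    ).all():
        raise ValueError("measurement values must be finite and > 0 mm")
    averaged = ag.average_repetitions(measurements)

    rows = []
    for comp in comparisons:
        name = comp.get("name") or "comparison"
        a = _select_series(averaged, comp["a"])
        b = _select_series(averaged, comp["b"])
        common = a.index.intersection(b.index)
        if len(common) < 2:
            raise ValueError(f"comparison {name!r}: fewer than 2 shared subjects")
        a, b = a.loc[common], b.loc[common]
        matrix = np.column_stack([a.to_numpy(), b.to_numpy()])
        icc = ag.icc_2_1(matrix, alpha=config.alpha, se_method=config.power_se_method)
        ba = ag.bland_altman(a, b, loa_multiplier=config.loa_multiplier,
                             keep_arrays=False)
        reg = ag.calibrate_regression(a, b)
        lo_disp, hi_disp = icc.ci_display
        rows.append(
            {
                "comparison": name,
                "n": icc.n,
                "icc": icc.icc,
                "ci_low": lo_disp,
                "ci_high": hi_disp,
                "power": icc.power,
                "classification": icc.classification,
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r2": reg.r2,
                "rmse": reg.rmse,
                "p_value": reg.p_value,
            }
        )
    report = pd.DataFrame(rows)
    if out_path is not None:
        report.to_csv(out_path, index=False)
    return report


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
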