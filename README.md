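# sasmorph

Subacromial-space (SAS) morphometry from bone segmentation masks, plus the
agreement statistics used to compare raters and imaging modalities that
measure it.

The SAS — the gap between the humeral head and the acromion — narrows in
subacromial impingement syndrome, and its width (in mm) is measured
clinically by ultrasound and quantified volumetrically from MRI. `sasmorph`
is for musculoskeletal imaging researchers who need both halves of that
workflow:

1. **Geometry.** Binary humerus/acromion masks (NIfTI) are Gaussian-smoothed
   (σ² = 1.56 mm² by default), triangulated by marching cubes, resampled to
   10,000 near-uniform vertices by Voronoi clustering, and ray-cast: from
   every acromion vertex a ray runs 50 mm along the outward normal, and the
   Euclidean distance to the first humerus intersection is recorded. Two
   summaries are derived — **MRI_Hum10**, the mean of the 10% closest
   distances, and **MRI_Lat**, the minimum distance from the most lateral
   acromion point to the humerus (what ultrasound can see). Heatmaps export
   as VTK/PLY with a per-vertex `sas_mm` scalar.

2. **Agreement.** For repeated width measurements (subject × rater ×
   position × repetition), the package computes ICC(2,1) — single-measure
   absolute agreement under the two-way random-effects model,

       ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

   — with its F-based 95% CI, post-hoc power for the test of ICC = 0 via
   the Fisher z transformation, Bland–Altman bias and limits of agreement,
   descriptive differences, and OLS calibration regressions
   (MRI = a + b·US with R², RMSE, overall-F p).

Because raw study data of this kind is rarely shareable, the package ships
two first-class synthetic generators: a sphere-plus-plate **phantom** with a
closed-form true gap (to validate the geometry end-to-end) and a two-way
random-effects **rater simulator** with a closed-form implied population
ICC (to validate the statistics). See `docs/methods.md` for the models and
conventions.

## Worked example

```bash
python examples/01_phantom_to_width_measures.py
```

```
phantom grid (60, 60, 68), true gap 9.50 mm
MRI_Hum10 = 9.28 mm   (mean of the 10% closest ray distances; truth 9.5 mm)
MRI_Lat   = 17.65 mm   (clearance at the most lateral acromion point)
2593 of 10000 acromion vertices reached the humerus within 50 mm
```

The pipeline recovers the analytic 9.5 mm gap to 0.22 mm at the 0.8 × 0.8 ×
1 mm protocol voxel size; `MRI_Hum10` sits slightly above the true minimum
because it averages the 10% closest points, which spread onto the humeral
head's shoulder. `MRI_Lat` is larger because the plate's lateral edge
overhangs the head — exactly the geometric reason a lateral (ultrasound-
like) width differs from the true minimum.

```bash
python examples/02_rater_agreement.py
```

```
simulated 108 rows; implied population ICC(2,1) = 0.872
ICC(2,1) = 0.63 [0.00-0.90], power = 0.87, moderate
bias = +1.21 mm, LoA [0.33, 2.10] mm
calibration: expert = -2.20 + 1.08 x novice, R^2 = 0.89, RMSE = 0.46 mm
```

An 18-subject, two-rater cohort with a 1.3 mm systematic novice
overestimate: the absolute-agreement ICC lands in the moderate band even
though the raters correlate strongly, and the bias reappears as the
Bland–Altman mean difference. `examples/03_power_analysis.py` tabulates
post-hoc power across the ICC range for this design.

There is also a thin CLI over the same functions:

```bash
sasmorph simulate --out work/ --gap-mm 9.5
sasmorph sas --humerus work/humerus.nii.gz --acromion work/acromion.nii.gz --out work/run/
sasmorph agree --measurements work/measurements.csv --comparisons comps.yaml --out report.csv
```

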