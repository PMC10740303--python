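"""Build a voxelized shoulder phantom and recover its subacromial width.

Generates a sphere-plus-plate phantom with a known 9.5 mm gap at the scan
protocol's 0.8 x 0.8 x 1 mm voxel size, runs the full surface pipeline
(Gaussian smoothing, marching cubes, 10,000-point resampling, 50 mm ray
cast) and prints the two width measures next to the analytic truth.
"""

import sasmorph as sm

spec = sm.PhantomSpec(gap_mm=9.5, voxel_spacing=(0.8, 0.8, 1.0))
humerus, acromion, true_gap = sm.generate_phantom(spec)
print(f"phantom grid {humerus.voxels.shape}, true gap {true_gap:.2f} mm")

measures, dmap, log = sm.masks_to_measures(humerus, acromion)

print(f"MRI_Hum10 = {measures.mri_hum10:.2f} mm   "
      f"(mean of the 10% closest ray distances; truth {true_gap:.1f} mm)")
print(f"MRI_Lat   = {measures.mri_lat:.2f} mm   "
      f"(clearance at the most lateral acromion point)")
print(f"{measures.n_valid} of {log['acromion_vertices']} acromion vertices "
      f"reached the humerus within 50 mm")

# MRI_Hum10 sits slightly above the true minimum because it averages the
# closest 10% of points, which spread onto the humeral head's shoulder;
# MRI_Lat is larger still because the lateral plate edge overhangs the head.
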