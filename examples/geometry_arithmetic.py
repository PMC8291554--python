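"""Derived quantities of the 45°-oblique on-the-fly scan.

Shows how magnification, voxel size, imageable depth, camera throughput
and motion blur follow from a handful of optical and scan parameters.
"""

from visor.geometry import (AcquisitionGeometry, VoxelGrid,
                            effective_magnification, imageable_depth,
                            motion_blur_extent, voxel_grid, voxel_throughput)

g = AcquisitionGeometry(objective_mag=20.0, tube_focal_mm=120.0,
                        stage_speed_um_s=1000.0, scan_rate_hz=200.0)
grid = voxel_grid(g)

print(f"effective magnification : {effective_magnification(g):.2f}x "
      "(20x objective behind a 120 mm tube lens)")
print(f"in-plane pixel          : {grid.pixel_um:.3f} um")
print(f"frame step              : {grid.frame_step_um:.2f} um of stage travel per frame")
print(f"axial plane spacing     : {grid.axial_step_um:.2f} um "
      "(frame step projected onto the plane normal)")
print(f"imageable depth         : {imageable_depth(420.0, 45.0):.0f} um "
      "from a 420 um oblique field — why slices are cut at 300 um")
print(f"voxel throughput        : {voxel_throughput(0.3e9, VoxelGrid(0.5, 5.0, 3.5)):.2e} vox/s "
      "at 0.3 mm^3/s (the camera caps out at 4e8)")
print(f"blur, synchronized scan : {motion_blur_extent(500.0, 100e-6):.3f} um "
      "(beam dwell ~100 us per voxel)")
print(f"blur, plain light sheet : {motion_blur_extent(500.0, 1 / 100):.1f} um "
      "(full 10 ms frame exposure at 0.5 mm/s — unusable)")
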