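"""Cube-grid geometry: areas, the optic-nerve-head mask, polar coordinates.

The device lays a 26x26 grid of 200 um cubes over the optic-disc scan; the
88 central cubes fall on the optic nerve head (ONH) and are excluded, leaving
588 analysed peripapillary cubes.
"""

from ppct import build_geometry, cube_polar, select_onh_mask

geometry = build_geometry()  # 26 x 26, 0.2 mm cubes, 88-cube ONH mask
mask = select_onh_mask(geometry)

print(f"cubes: {geometry.n_cubes} total, {mask.count} ONH, "
      f"{geometry.n_analyzed} analysed")
print(f"areas: total {geometry.total_area:.2f} mm^2, "
      f"ONH {geometry.onh_area:.2f} mm^2, "
      f"effective {geometry.effective_area:.2f} mm^2")

# polar coordinates of the cube the device displays as row 9, column 9
radius, angle = cube_polar(geometry, 9, 9, laterality="OD")
print(f"cube (9, 9): {radius:.2f} mm from the grid centre at {angle:.0f} deg "
      f"(90 = superior, 0 = temporal for a right eye)")

# The effective area (total minus ONH) is the denominator used when regional
# mean thickness is converted to choroidal volume.
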