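"""Interpolate per-field cell counts into a retinal density map.

Fields are sampled along the horizontal and vertical meridians crossing
the optic nerve.  Placing each field's cell count at its retina
coordinates and interpolating linearly yields a density map; a hotspot
planted in the inferior arm shows up as the map maximum.
"""

import numpy as np

from gliacount import build_density_map, trimmed_group_summary

layout, counts = {}, {}
rng = np.random.default_rng(5)
for i, t in enumerate(np.linspace(-4, 4, 9)):
    layout[f"h{i}"] = (t, 0.1 * (-1) ** i)       # horizontal meridian
    layout[f"v{i}"] = (0.1 * (-1) ** i, t)       # vertical meridian
    counts[f"h{i}"] = int(rng.integers(12, 18))
    counts[f"v{i}"] = int(rng.integers(12, 18))
counts["v0"] = 35  # inferior-retina hotspot

dm = build_density_map(counts, layout, resolution=60)
iy, ix = np.unravel_index(np.nanargmax(dm.grid), dm.grid.shape)
print(f"fields                 : {len(counts)}")
print(f"count range            : {min(counts.values())}-{max(counts.values())} cells/field")
print(f"map maximum            : {np.nanmax(dm.grid):.1f} cells/field "
      f"at (x={dm.x_coords[ix]:.2f}, y={dm.y_coords[iy]:.2f})")
print(f"hotspot field location : (x={layout['v0'][0]:.2f}, y={layout['v0'][1]:.2f})")

summary = trimmed_group_summary(list(counts.values()), k=2)
print(f"trimmed summary (k=2)  : n={summary.n}, median={summary.median:.1f}, "
      f"IQR=[{summary.q25:.1f}, {summary.q75:.1f}]")
# The interpolated maximum coincides with the hotspot field: the map
# passes exactly through the per-field counts.
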