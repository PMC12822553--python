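"""Map the refractive index along a fibril and decompose its variance.

Builds an analysis-level synthetic cross-section table whose true
refractive index fluctuates on a 250 nm scale, maps n in overlapping
100-localization windows against the AFM height, and splits the map
variance into experimental noise and genuine sample fluctuations.
"""
import numpy as np

from rimap.fibril import map_ri_along_fibril, variance_decomposition
from rimap.synth import synthetic_cross_section_table

rng = np.random.default_rng(4)
n_grid = [1.38, 1.40, 1.42, 1.44, 1.46, 1.48]
cell = 250.0  # correlation length of the index fluctuations, nm
offsets = rng.normal(0.0, 0.02, 64)
n_profile = lambda s: 1.43 + offsets[(s // cell).astype(int) % 64]

cs = synthetic_cross_section_table(n_grid, rng, axis_length=12000.0,
                                   n_profile=n_profile)
z_cols = {n: f"z@{n:.3f}" for n in n_grid}
maps = {}
for window in (100, 200, 400):
    maps[window] = map_ri_along_fibril(
        cs, n_grid, z_cols, afm_height=lambda s: 69.0,
        window_nlocs=window, overlap_fraction=0.9,
        n_resamples=100, n_draws=1000, rng=rng)
    print(f"window {window:3d} locs: {len(maps[window]):3d} map points, "
          f"mean extent {maps[window].window_nm.mean():6.0f} nm")

table = variance_decomposition(maps)
print("\nwindow  distance_nm  var_total   var_exp    var_collagen")
for row in table.itertuples(index=False):
    print(f"{row.window_nlocs:5d}  {row.mean_distance_nm:10.0f}  "
          f"{row.var_total:.2e}  {row.var_exp:.2e}  {row.var_collagen:.2e}")
print(f"\ninjected sample variance: {np.var(offsets):.2e}; small windows")
print("resolve it, large windows average the fluctuations away.")
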