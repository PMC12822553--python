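"""Localize blinking emitters in a small synthetic stack and merge blinks.

Renders a few frames of two well-separated dyes on glass, runs detection
and Poisson MLE fitting, links the repeated appearances, and prints the
standard error of the mean of the merged positions (the localization
precision of the merged signal).
"""
import numpy as np

from rimap.localize import localize_stack, merge_blinks
from rimap.optics import EmitterState, LayeredSample, MoleculeImageModel, OpticalSystem

rng = np.random.default_rng(0)
system = OpticalSystem(oversampling=2, pupil_samples=64)
glass = LayeredSample(n_layer=1.33, thickness=0.0)
model = MoleculeImageModel(system, glass)

frames = []
positions = [(8, 8), (8, 28)]  # pixel positions, > 2 ROIs apart
for _ in range(12):
    canvas = np.full((40, 40), 20.0)
    for r, c in positions:
        psf = model.psf(0.0, 0.0, 0.0)
        canvas[r - 7:r + 8, c - 7:c + 8] += 4000.0 * psf
    frames.append(rng.poisson(canvas))
stack = np.array(frames, dtype=float)

locs = localize_stack(stack, system, glass, absolute_threshold=500.0)
print(f"{len(locs)} localizations over {len(stack)} frames")
merged = merge_blinks(locs, linking_radius=100.0, max_gap=2)
for row in merged.itertuples(index=False):
    print(f"merged dye at ({row.x_nm:7.1f}, {row.y_nm:7.1f}) nm, "
          f"z = {row.z_nm:6.1f} nm, sem_z = {row.sem_z:.2f} nm "
          f"from {row.n_observations} appearances")
print("\nsem_z is the axial precision of the merged position; it shrinks")
print("with the square root of the number of linked appearances.")
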