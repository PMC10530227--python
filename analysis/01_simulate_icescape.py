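"""Simulate the synthetic circum-Antarctic icescape.

Generates the default 8-year, 15-day-cadence fast-ice stack on a
32 x 3520 five-km grid (an ~11,000 km coastline), the shelf-break
bathymetry, and the emperor/Adélie/Weddell colony points, and reports
what was produced.  Ground truth (latent class per pixel) is kept for
the recovery checks in later steps.
"""

import numpy as np

from common import ICE_CONFIG, RESULTS, STACK_NPZ, ensure_dirs
from icehab import generate_bathymetry, generate_icescape

ensure_dirs()

grid, truth = generate_icescape(ICE_CONFIG)
depth = generate_bathymetry(ICE_CONFIG)

np.savez_compressed(
    STACK_NPZ,
    values=grid.values.astype(np.float32),
    epoch_dates=grid.epoch_dates.astype("datetime64[D]").astype(np.int64),
    mask=grid.mask,
    cell_km=grid.cell_km,
    depth=depth,
    class_map=truth.class_map,
)
truth.colony_points.to_csv(RESULTS / "colony_points.csv", index=False)

emp = truth.colony_points.query("species == 'emperor'")
print(f"stack: {grid.values.shape} (epoch, row, col), {grid.epoch_dates[0]} .. {grid.epoch_dates[-1]}")
print(f"ice fraction range: {grid.values.min():.2f} .. {grid.values.max():.2f}")
print(f"bathymetry: {depth.min():.0f} .. {depth.max():.0f} m")
print(f"colonies: {len(emp)} emperor (spacing ~{np.diff(np.sort(emp.x_km)).mean():.0f} km), "
      f"{(truth.colony_points.species == 'adelie').sum()} Adélie, "
      f"{(truth.colony_points.species == 'weddell').sum()} Weddell")
print(f"latent classes: {len(truth.true_params)} longitudinal bands")
print(f"wrote {STACK_NPZ.name} and colony_points.csv")
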