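"""Assemble the 13-variable habitat feature table with presence labels.

Joins the seven fast-ice metrics with depth, slope, distance to the
-800 m isobath and the three nearest-colony distances on the 5-km grid,
labels cells within 3 km of an emperor colony as presences, and drops
masked cells.
"""

import numpy as np
import pandas as pd

from common import FEATURES_CSV, RESULTS, STACK_NPZ, METRICS_NPZ, ensure_dirs
from icehab import build_feature_table
from icehab.features import FEATURE_COLUMNS
from icehab.metrics import FastIceMetrics

ensure_dirs()
stack = np.load(STACK_NPZ)
m = np.load(METRICS_NPZ)
mets = FastIceMetrics(
    persistence=m["persistence"], volatility=m["volatility"],
    timing_max_code=m["timing_max_code"], timing_min_code=m["timing_min_code"],
    magnitude=m["magnitude"], trend=m["trend"], extent_km=m["extent_km"],
    cell_km=float(m["cell_km"]),
)
colonies = pd.read_csv(RESULTS / "colony_points.csv")

table = build_feature_table(mets, stack["depth"], colonies)
table.to_csv(FEATURES_CSV, index=False)

pres = table["is_presence"]
desc = table.loc[pres, FEATURE_COLUMNS].describe().loc[["mean", "std", "min", "max"]]
desc.round(3).to_csv(RESULTS / "presence_variable_summary.csv")

print(f"feature table: {len(table)} cells "
      f"(M = {int(pres.sum())} presence, N = {int((~pres).sum())} absence)")
print("\npresence-cell variable ranges:")
print(desc.round(2).T.to_string())
print(f"\nwrote {FEATURES_CSV.name} and presence_variable_summary.csv")
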