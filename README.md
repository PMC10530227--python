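# icehab — emperor-penguin habitat structure on Antarctic landfast ice

Emperor penguins (*Aptenodytes forsteri*) breed almost exclusively on
landfast sea ice — coastal ice held stationary by ice shelves and
grounded icebergs.  Whether "emperor penguin habitat" is one type of
environment or several regionally distinct ones matters for projecting
the species' fate under sea-ice change.  `icehab` implements a
circumpolar, presence/absence habitat analysis for researchers in
statistical ecology and sea-ice science: it derives fast-ice phenology
metrics from 15-day raster time series, characterises every 5-km
coastal cell by 13 environmental variables, and asks whether occupied
sites fall into distinct habitat clusters — and how close any cell is
to optimal habitat.

## The analysis

Starting from a fast-ice fraction stack (15-day cadence, multi-year),
seven per-pixel metrics are computed: **persistence** (mean ice
residence, 0–100%), **volatility** (RMS of the residual after removing
a 3-point, ≈45-day boxcar), **magnitude of the annual cycle** (range of
a 4th-order annual Fourier fit, period 365.25 d, to 13-point smoothed
data), **timing of the seasonal maximum and minimum** (days of year
coded −5…+5 between fixed anchor dates, discarded where magnitude
< 0.4), the linear **trend** (fraction yr⁻¹), and October **extent**
(km, median coastal band width).  Six covariates join them: depth,
bathymetric slope (degrees), distance to the −800 m isobath, and
distances to the nearest emperor, Adélie and Weddell-seal colony.

Cells within 3 km of an emperor colony are *presences* (M rows); all
other fast-ice cells are *absences* (N rows).  Four steps follow:

1. **PCA** on the correlation matrix of the presence rows (variables
   standardized by presence mean/s.d.); the leading Q = 4 axes define
   the habitat space.
2. **Model-based clustering** of the presence scores with a Gaussian
   mixture p(x) = Σₖ πₖ φ(x; μₖ, Σₖ) under the **VEI** covariance
   structure — diagonal Σₖ = λₖB with per-component volume λₖ and one
   shared shape B, det(B) = 1 — fit by multi-start EM for K = 2…7 and
   selected by BIC.  Each observation gets a posterior membership
   p(zₙ = k | xₙ), an accuracy aₙ = maxₖ p(zₙ = k | xₙ) and an
   uncertainty uₙ = 1 − aₙ.
3. **Projection** of the absence rows into the presence PC space and
   soft assignment to the presence clusters.
4. **HDR closeness**: for each cell, pₙ is the probability mass of
   Dₙ = {x : p(x) ≥ p(xₙ)} under the fitted mixture (Monte-Carlo, with
   a trapezoidal-grid cross-check in low dimension), and cₙ = 1 − pₙ
   measures closeness to optimal habitat (1 at the density mode, → 0
   far from all mass).

Because the source satellite rasters and colony coordinates are not
redistributable, the package ships a first-class synthetic generator
(`icehab.synthetic`) that emulates the study conditions — seasonal
fast-ice cycles with AR(1) noise and breakout events over latent
regional classes, a shelf-break bathymetry, and colony points spaced
~220 km along the coast — with known ground truth for recovery testing.

## Worked example

```python
from icehab import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
m = result.manifest
print(m["n_presence"], m["n_absence"], m["selected_K"], m["presence_truth_ari"])
```

prints `80 91440 5 1.0`: 80 presence cells (one per synthetic emperor
colony) against 91,440 fast-ice absence cells; BIC over K = 2…7 selects
**K = 5** clusters, and the maximum-a-posteriori presence clusters
recover the generator's five latent habitat classes with adjusted Rand
index **1.0**.  The numbered scripts under `analysis/` run the same
study step by step and write tables under `results/`; on the default
icescape they report

```
selected K = 5 by BIC (loglik -351, BIC 843, ICL -843, n = 80, df = 32)
BIC by K: {2: 1128.0, 3: 1052.0, 4: 968.0, 5: 843.0, 6: 852.0, 7: 866.0}
presence cells assigned at 80% certainty: 80/80; at 59%: 80/80
HDR closeness c_n: presence median 0.47, absence median 0.00
```

i.e. every colony is confidently assigned a habitat cluster, presence
cells sit inside the high-density core of the fitted habitat
distribution (median cₙ = 0.47) while typical absence cells are far
outside it (median cₙ ≈ 0), and the df = 32 of the selected model is
the VEI parameter count for K = 5 components in 4 dimensions
(20 means + 4 weights + 5 volumes + 3 shape entries).

Run the scripts in order from `analysis/`:

```
cd analysis
python 01_simulate_icescape.py     # stack, bathymetry, colonies
python 02_fastice_metrics.py       # the seven per-pixel metrics
python 03_feature_table.py         # 13-variable table, presence labels
python 04_habitat_pca.py           # step I: presence PCA
python 05_cluster_habitats.py      # steps II-III: VEI mixture, projection
python 06_closeness_and_comparisons.py  # step IV: HDR closeness, tests
```

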