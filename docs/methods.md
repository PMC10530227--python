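# Methods

This note documents the models and procedures implemented in `icehab`,
the parameter choices that matter, what the synthetic data generator
does and does not emulate, and the numerical conventions used
throughout.

## Fast-ice metrics

All seven metrics are strictly per-pixel functions of a fast-ice
fraction series at 15-day cadence; no spatial information enters before
the final aggregation step.

**Boxcar smoothing.** Centered moving average with an odd window; edges
use the mean of the points available inside the shrinking window, and
missing epochs are excluded from every average rather than
interpolated.

**Volatility** is the RMS of (series − 3-point boxcar), computed over
interior epochs only. The 3-point (~45-day) smoother removes the
seasonal signal, so the residual isolates short-timescale variability;
for fraction-valued series the result lies in [0, 1] (an alternating
0/1 series gives exactly 2/3 at interior points).

**Persistence** is 100 × the mean over valid epochs.

**Annual cycle fit.** A 4th-order Fourier series with fundamental
period 365.25 days is fit to the 13-point (~6-month) boxcar-smoothed
series. The model is linear in its coefficients, so an ordinary
least-squares solve reaches the same optimum an iterative
Levenberg–Marquardt minimiser would; we use the direct solve. The
fitted curve is evaluated at daily resolution over one folded year to
locate the climatological day of maximum and minimum (ties break to the
earliest day) and the annual **magnitude** (max − min, clipped to
[0, 1]).

A deliberate consequence of fitting the *smoothed* series: the 13-point
boxcar attenuates the annual harmonic by ~0.59 at 15-day cadence, so
the magnitude of a raw cycle of amplitude A is ≈ 1.19·A rather than
2·A. The package reports the magnitude of the smoothed fit, and the
0.4 discard threshold for timing codes (below) operates on that same
scale. The tests pin this behaviour with an oracle that smooths a pure
sinusoid directly.

**Timing codes.** The timing of the maximum maps Jul 15 → −5,
Sep 15 → 0, Dec 15 → +5 (minimum: Dec 15 → −5, Mar 15 → 0,
May 15 → +5) by piecewise-linear interpolation on the circle between
the anchor dates, clamped to [−5, 5]. Wherever the annual-cycle
magnitude is below 0.4 the code is multiplied by 0: where the cycle is
weak, its phase is noise. Anchors sit on the 15th of each anchor month
because only the months are specified; interpolation and clamping are
the package's choices.

**Trend** is the OLS slope of fraction against time in years. Note a
finite-sample caveat pinned in the tests: the OLS slope of a pure
sinusoid over whole cycles is not identically zero but decays as
6·A·p/(π·T²) — below 1e-3 yr⁻¹ only once the record is a few decades
long.

**Extent.** For each year the first epoch falling in Oct 1–15 is
binarized at 0.5; along each grid column the width (km) of the
contiguous ice band attached to the coast row is assigned to every cell
in the band and 0 elsewhere; the per-cell extent is the median across
years. Measuring along grid columns from the coast row is the synthetic
convention (a real-data path would walk meridians); the per-cell
meaning of "extent in km" is otherwise under-determined, and this
band-width reading is flagged as such.

**Masking and aggregation.** Pixels with persistence below 1e-6
(fraction scale) are masked; block means over valid pixels aggregate
native grids to the 5-km analysis grid (the synthetic generator emits
5-km grids directly, so the default factor is 1). A block with no valid
pixel stays masked.

## Geographic and biological covariates

Slope is atan(‖∇z‖) in degrees from central differences of the depth
grid over the cell spacing. The −800 m isobath is traced by
marching-squares contouring with linear interpolation along cell edges;
distances are planar on the km-grid (a haversine helper, R = 6371 km,
covers lon/lat inputs). Nearest-colony distances use a KD-tree; for the
distance-to-nearest-emperor variable at presence cells, the colony
defining the cell is excluded (distance to the nearest *other* colony),
otherwise the variable is ≈ 0 for every presence row and carries no
information. Presence cells are those whose centroid lies within 3 km
of an emperor colony; the absence-buffer sensitivity analysis drops
absences within 10/20/30 km of any colony and re-runs the tests.

## PCA of the presence data

The PCA is run on the correlation matrix of the presence rows only:
variables are standardized by presence means and standard deviations
(n-denominator, so score variances equal eigenvalues), giving each
variable equal weight. Eigenvector signs follow a deterministic
convention (largest-|loading| entry positive). Contributions are
100·loading², per axis; cos² is loading²·λ, the squared correlation
between variable and score. Absence rows are projected with the
*presence* standardization — the habitat space is shaped by occupied
sites, and distance from the presence cloud is the quantity of
interest. Q = 4 axes are retained by default (configurable).

## VEI Gaussian mixture

Component covariances are Σₖ = λₖB with B diagonal and det(B) = 1:
clusters share one shape but differ in volume. Free parameters:
K·d + (K−1) + K + (d−1); for K = 5, d = 4 this is 32.

The M-step has no closed form for (λ, B) jointly; the package iterates
the fixed point B ∝ Σₖ Wₖ/λₖ (normalized to unit determinant via the
geometric mean), λₖ = Σⱼ Wₖⱼ/Bⱼ/(d·nₖ), where Wₖ is the diagonal
weighted scatter, to a relative tolerance of 1e-8. EM stops when the
relative log-likelihood change falls below 1e-8 or at 1000 iterations;
monotonicity is asserted every iteration. Ten k-means-seeded starts are
run per K (fixed RNG), keeping the best converged log-likelihood. A
component whose effective size falls below d, or whose volume falls
below 1e-12, aborts that start; if all starts collapse, fitting fails
loudly. Fitting requires n > df.

Model selection minimises BIC = −2·loglik + df·ln n over K = 2…7 (K = 1
is excluded from the default range; `fit_vei` still accepts it, which
the single-Gaussian closed-form tests use — at the K = 1 optimum,
det(B) = 1 forces λ to equal the geometric mean of the per-axis
variances). BIC is reported on this positive penalised-deviance scale
and also stored signed (2·loglik − df·ln n); ICL is the signed BIC
minus twice the posterior entropy, so ICL ≤ signed BIC with equality
for a crisp partition. Both conventions are written into the model
JSON.

Assignments: posterior matrix, MAP label (ties to the lowest index),
accuracy aₙ = max posterior, uncertainty uₙ = 1 − aₙ, a threshold
label (−1 where aₙ < τ; defaults τ = 0.80 strict, τ = 0.59 relaxed),
and a dual-membership flag where two or more posteriors reach τ — only
possible for τ ≤ 0.5, which is why the flag matters at relaxed
thresholds, where an observation can qualify for two clusters at once.

Two independent routes check the EM optimum in the tests: a generic
Nelder–Mead optimization of the VEI likelihood in an unconstrained
parameterization, and the VEI family of R's `mclust`, run via Rscript
on the same data; both must agree with the package's log-likelihood.

## HDR closeness

For a fitted mixture p and a point xₙ, Dₙ = {x : p(x) ≥ p(xₙ)} and
pₙ = P(X ∈ Dₙ); cₙ = 1 − pₙ. The default estimator is Monte Carlo with
S = 200,000 mixture draws and a fixed recorded seed: p̂ₙ is the
fraction of draws whose density is at least p(xₙ) (ties inside, a
measure-zero event), with standard error √(p̂(1−p̂)/S) reported per
point. A trapezoidal grid integrator over a ±9-marginal-σ box is
provided for d ≤ 2 as a cross-check. Grid integration in the full 4-D
space was rejected as the default: at feasible resolutions it is both
slower and biased, whereas Monte Carlo is unbiased with a quantified
error. For a single Gaussian the closed form pₙ = χ²_d CDF of the
squared Mahalanobis distance serves as an exact oracle in the tests.

## Cluster reporting and tests

Summaries (median, sample SD, n) are computed per cluster × variable ×
presence-status over rows with aₙ ≥ τ; single-member groups have
missing SD and empty clusters appear with n = 0. Group comparisons are
nonparametric — the bounded, skewed metrics (fractions, distances,
codes with point masses) argue against normal-theory tests: per
variable a Kruskal–Wallis test across clusters followed by pairwise
two-sided Mann–Whitney tests, Holm-adjusted within the variable; and
per cluster a presence-vs-absence Mann–Whitney per variable,
Holm-adjusted across variables, at α = 0.05. Groups with n < 2 are
skipped with a note. The buffer sensitivity analysis reports which
significance decisions flip after absence removal at each buffer.

## The synthetic icescape

The generator produces the study's inputs with known truth. Per pixel,

    f(t) = zone(y) · clip(m + A·sin(2π(d(t) − φ)/365) + e(t), 0, 1)

with class persistence m, amplitude A, peak day φ + 91.25, AR(1) noise
e (coefficient 0.5, stationary sd per class) and breakout events that
zero 2–6 consecutive epochs with a per-year probability. zone(y) ramps
from 1 at 80 km offshore to 0 at 130 km: landfast ice is a coastal
phenomenon, and this keeps absence cells inside a realistic fast-ice
zone over the shelf (≈ 91k five-km absence cells on the default
domain) rather than over abyssal water. Latent classes are contiguous
longitudinal bands, mimicking regional geographic structure.

The five default classes were designed so that every pair is well
separated on at least one metric relative to its within-class spread —
the condition under which latent habitat structure is recoverable at
all:

| class | m | A | peak doy | noise sd | breakout/yr | signature |
|---|---|---|---|---|---|---|
| 0 | 0.50 | 0.48 | 200 | 0.06 | 0.2 | strong early-peaking cycle |
| 1 | 0.50 | 0.48 | 316 | 0.06 | 0.2 | strong late-peaking cycle |
| 2 | 0.20 | 0.10 | 258 | 0.04 | 0.1 | quiet low-persistence ice |
| 3 | 0.35 | 0.15 | 285 | 0.18 | 0.7 | volatile breakout regime |
| 4 | 0.85 | 0.20 | 258 | 0.03 | 0.05 | near-permanent multiyear ice |

Three design points deserve explanation. First, annual-cycle
magnitudes are kept well clear of the 0.4 timing-discard threshold on
both sides: a class whose magnitude straddles 0.4 gets bimodal timing
codes (some pixels zeroed, some not), which inflates within-class
variance and defeats clustering. Only the two strong-cycle classes
carry timing information; they are separated by phase alone. Second,
the shelf profile is scaled per class (`class_depth_factors`, spread
over [0.75, 1.25] and interleaved so neighbouring bands contrast): real
Antarctic sectors differ bathymetrically, and without this the six
geographic/biological covariates are pure noise at unit z-variance each,
which drowns the ice signal in the leading PCs. Third, the default
coastline (3520 × 5 km ≈ 11,000 km, ~80 colonies at ~220 km spacing,
with ±15% scatter in the spacing) yields a presence sample large enough
that BIC (penalty df·ln n, df = 32–44 for K = 5–7 in d = 4) can resolve
the true K; each colony is jittered within 1.5 km of a coast-row cell
centroid, so it marks exactly one presence cell under the 3-km rule.

What the generator does **not** emulate: cloud gaps and polar-night
data loss, map projections and latitude-dependent cell geometry,
spatially correlated noise between pixels, colony-size effects, and
multi-cell colonies. Passing recovery tests therefore show that the
pipeline's statistics behave correctly under the stated data-generating
model — not that real MODIS-derived data meet that model.

## Problem sizes and runtimes

The default end-to-end run (32 × 3520 grid, 192 epochs, ~91k scored
cells) completes in about two minutes on one CPU; the test suite uses a
smaller 12 × 1100 / 4-year configuration for pipeline unit tests and
the full default only for the end-to-end recovery check. Parameter
recovery tests use n = 2000 points in d = 4 over ten replicates. These
sizes were chosen to keep the whole suite comfortably interactive while
leaving the statistical conclusions unchanged at larger n.

## Known limitations

- The magnitude scale is tied to the 13-point smoothing (see above);
  comparisons with magnitudes computed from raw series need a ≈1.19/2
  rescaling.
- The HDR mass for K > 1 has no closed form; the Monte-Carlo error is
  quantified but not zero, and very small cₙ differences (≪ 4·SE) are
  not resolvable.
- With n in the low hundreds, BIC occasionally prefers K ± 1 around a
  weakly separated truth; the BIC table is always written so such calls
  can be reviewed.
- The absence cells of the synthetic world differ from presences partly
  through geography (they extend offshore); within-cluster
  presence-absence comparisons on synthetic data reflect that
  construction, not a biological claim.
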