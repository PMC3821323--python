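# Methods

This note records the modelling choices behind `cbmap`: what each component
assumes, which parameters matter and why their defaults are what they are,
what the synthetic field does and does not emulate, and the numerical
decisions a careful user should know about.

## Coordinate frame and grids

All mapping happens in a Local Tangent Plane (LTP): a Cartesian
east/north/up frame tangent to the WGS84 ellipsoid at a user-chosen field
origin. Geodetic positions are converted through Earth-centered Earth-fixed
coordinates and rotated into the tangent plane; the inverse uses a
fixed-point iteration on latitude that converges far below 1 mm for
terrestrial points. Altitudes are ellipsoidal throughout — no geoid
correction is applied, which is harmless because only *relative* elevation
within a field (a few hundred metres across) ever enters the analysis.

Grid cells are squares of side `cell_size` (default 4 m, giving the 16 m²
working unit in which yield is expressed). Indexing is 0-based with
half-open intervals `[k·s, (k+1)·s)`: every point on a shared edge belongs
to exactly one cell, so there is no boundary ambiguity. Column index grows
eastward, row index northward. Grid dimensions are configuration, not
derived from field geometry, because sampled rows rarely tile the grid
exactly.

A missing cell is a first-class state (NaN plus a zero observation count),
never a zero. Empty cells are left empty — no interpolation or kriging —
because a cell with no data carries no information and later passes can fill
it. The display sentinel 1 available when exporting QPI maps exists purely
to make missing cells legible on a color scale whose observed values stay
below ~0.8; it never enters computation.

**Rasterization** reduces the samples inside each cell with the mean
(default) or the maximum (for applications that label cells by top values).
The mean reducer conserves "sample mass": the count-weighted sum of cell
values equals the sum of in-grid sample values, a property the tests assert.

**Downsampling** merges `factor × factor` blocks. Children are weighted by
their observation counts, which makes the operation exactly equivalent to
re-rasterizing the original samples on the coarse grid; an unweighted mode
exists for maps without meaningful counts. Ragged edges are allowed (edge
blocks simply have fewer children), an output cell is missing only when all
children are, and units are left untouched — a yield map in kg per 16 m²
keeps those units at 8 m resolution so maps of different cell size remain
directly comparable.

## Statistical nature of traits

Regression, ANOVA and t inference all assume approximately normal errors, so
each trait is checked before modelling. The check is the correlation
`r_qq` between the sorted standardized data and standard-normal quantiles at
plotting positions `(k − 0.5)/n` — the linearity of the normal Q–Q plot.
The plotting-position convention is pinned for reproducibility; the
alternative `k/(n+1)` differs negligibly at the sample sizes involved
(n ≈ 150–300). The qualitative rating discretizes `r_qq`: *very strong* at
≥ 0.995, *strong* at ≥ 0.98, *weak* below. These thresholds are
configurable; the defaults were chosen so that an exactly-normal sample
rates very strong, a linear terrain ramp rates weak, and ordinary normal
samples of n ≈ 200 rate strong or better — the qualitative pattern expected
of the reference traits.

Outliers are detected with studentized deleted residuals: each residual is
scaled by an error variance estimated with that observation left out, so an
outlier cannot inflate its own yardstick. The default flag threshold is the
two-sided t quantile at Bonferroni-corrected level `0.05/n` with `n − p − 2`
degrees of freedom. The policy is identification only — flagged observations
are reported, never silently removed.

## Model families, metrics and selection

Candidate models are declared symbolically (terms like `X1`, `X1^2`,
`ln(X1)`, `1/X1`, `X1*X3`) and fitted by ordinary least squares on the
transformed design; the power family `y = a·x^b` is intrinsically nonlinear
and is fitted by nonlinear least squares on the original response scale,
initialized from a log–log OLS fit (tolerances 1e-10). Fitting on the
original scale matters: a log–log fit minimizes relative error and its R²
refers to the transformed response, which is not comparable across
candidates. Both R² and the resistant R² are therefore always computed on
the original scale, for every family.

The resistant R² replaces the sums of squares with medians of absolute
deviations, centering on the sample median. The center is the median (not
the mean) deliberately; a configuration switch to the mean exists for
sensitivity checks, and the difference is itself informative about outlier
load. The score is undefined when the median absolute deviation of the
response is zero (more than half the observations identical), which is
raised as a domain error rather than silently returned.

Degenerate exact fits are handled explicitly: a zero error sum of squares
yields an infinite F statistic, and numerically-exact regressions produce
all-zero studentized deleted residuals (there is nothing to studentize).

Rows with a missing value in any required trait are dropped listwise; the
regression unit is the grid cell, and correlation happens only among cells
that store data. Reciprocal and logarithmic terms require strictly positive
predictors; zero-vigor cells are excluded from those families by a domain
error rather than fudged.

**Selection** is lexicographic, mirroring how a field analyst actually
reasons: (1) discard candidates with any term non-significant at the 95%
level — a model carrying a dead predictor is not simplified, it is rejected;
(2) discard candidates failing physical boundary checks (the yield model
must pass near the origin: no vegetation, no yield); (3) rank survivors by
resistant R², breaking ties by the ANOVA F statistic and then by parsimony.
Every discard and rank is logged in an audit trail. No multiple-testing
correction is applied across candidates, matching standard practice for
this kind of exploratory model screening. If every candidate fails the
filters the ranking falls back to the full set (with the failures on
record) so a winner is always defined.

**Coherence analysis** correlates two measurements of the same underlying
trait (e.g. vigor from an 8 mm vs a 12 mm lens) with linear, quadratic and
cubic families, and raises a *regression fallacy* flag when the variance
ratio of the pair exceeds 0.5: with similar variances, a slope below one is
the arithmetic consequence of |r| ≤ 1, not evidence that one measurement
attenuates the other. The 0.5 threshold is a deliberate round number — the
reference soil-resistance pair (variance ratio ≈ 0.23) must not flag, while
identical traits (ratio 1) must.

## The Quality Potential Index

The QPI condenses the two classical ripeness balances for red grapes —
Brix:TA near 30 and Brix·pH² near 260 — into one common-log score,
`QPI = 2·log10(pH·Brix) − log10(780·TA_gL)`, zero at perfect balance and
approximately symmetric around it. Common (not natural) logarithms keep the
score within [−1, 1] for physiological musts. The constant is 780 with
acidity in g/L and 7800 with titratable acidity in g/100 mL; the two forms
are algebraically identical and the tests assert the identity on 10⁴ random
inputs, so a transcription slip in either constant is impossible.

At the textbook optimum (pH 3.4, TA 7.5 g/L, 22 Brix) the balance product is
(3.4·22)²/5850 = 0.9564, a hair *under* 1, so the score is −0.019: a
magnitude of 0.02, which in practice is the optimum. The sign is informative
(acid marginally dominating sugar) and the package reports it; summaries
that quote the deviation from optimum use the magnitude.

Map-level QPI is computed *average-then-score*: cell chemistry is averaged
first and the score taken second, so a cell's QPI is the QPI of its mean
must. A score-then-average mode is deliberately not offered — the two do not
commute through the logarithm, and offering both invites silent
inconsistency between maps.

## The control biosystem

The biosystem packages the selected yield and quality models behind a single
input: the V-8 vigor map. Predictions outside the fitted vigor interval
[0, 100] raise an extrapolation error — a statistical model has no validity
claim outside its working interval, so extrapolation is refused rather than
warned about. Whole-map application skips (and warns about) out-of-range
cells and propagates missing cells unchanged; prediction commutes with cell
masking, which the tests assert.

Frozen reference coefficient sets are shipped as presets (`requena-2013`,
`requena-2013-low` for the 8 m refit), so the canonical worked numbers —
6.3 and 5.6 kg/16 m² at full coverage, QPI 0.289 at zero vigor and −0.41 at
full, quality optima at 41% and 43% vigor — are pinned independently of any
refit. `compare_predictions` scores a prediction map against measurements
cell-wise and additionally reports the relative error at the measured
maximum, the quantity by which the power law's known underestimation of peak
yield (25% at the reference field) is tracked.

## The synthetic vineyard

The generator emulates the reference field campaign: ten trellised rows,
130 m long, 3 m apart, on a 3% slope falling eastward, with 219 sampling
stations (the published station count; the implied ~5.9 m station spacing
follows from it). Per-trait marginals are calibrated to the published
summary statistics: vigor V-8 ~ N(39.5, 14.8²) truncated to [1, 100], soil
resistance N(2.74, 0.68²) with the maximum generated from the average by the
published linear relation, Baumé 13.1, total acidity 7.5 g/L, pH 3.3, berry
weight 9.4 g and diameter 11 mm, with density derived from the sphere
volume. Elevation is the deterministic slope ramp plus small roughness —
deliberately non-normal, since it is a terrain profile, not a random
variable. All truncation is by rejection sampling except vigor, whose
smoothed field is clipped at the physical limits.

Structural choices worth knowing:

- **Spatial structure.** Vigor is smoothed along rows with a moving-average
  window of 5 stations (configurable), then re-centred and re-scaled so the
  marginal mean and sd are calibrated exactly; without the recentering, the
  autocorrelation lets the realized mean wander several vigor points from
  seed to seed. Other traits inherit spatial structure only through their
  vigor coupling.
- **Yield.** `Y = 0.5724·V8^0.5212 + ε` with ε ~ N(0, 1.3²) truncated to
  (0.05, 12). The noise level is set so the cell-level power fit explains
  ~30% of yield variance, matching the reference fit strength (R² ≈ 0.37);
  the resulting marginal sd (~1.5) sits inside the published calibration
  band around 1.84. The two published figures — marginal spread and fit
  strength — cannot both be reproduced by a pure power-plus-noise model,
  because the field's extra marginal variance comes from spatial structure
  the generator does not emulate; fit strength is the binding quantity for
  parameter-recovery testing, so it wins. The wide truncation interval
  matters: tighter bounds visibly bias the conditional mean of the
  generating law at low vigor, corrupting the ground truth that recovery
  tests compare against.
- **V-12 vigor.** Generated from V-8 through a mild monotone cubic
  (13 + 0.62·V8 + 0.0045·V8² + 1.2e-5·V8³) plus noise (sd 8). The published
  cubic between the two lenses is printed too coarsely to be invertible (its
  cubic coefficient has one significant figure and the curve turns over
  within the observed range), so the generator uses its own relation with
  the same qualitative physics: the narrow lens always reports more
  vegetation, and the relationship is genuinely curved, which is what the
  coherence tests exercise.
- **Chemistry–vigor coupling.** Baumé, acidity and pH are tilted linearly in
  (V8 − 39.5) with slopes −0.0355 °Bé, +0.04 g/L and −0.009 pH per vigor
  point. These were derived analytically from the QPI differentials so that
  the implied QPI-on-vigor line has slope ≈ −0.007 and intercept ≈ 0.289 —
  the reference quality model — while each chemistry marginal keeps its
  published sd (base noise is reduced to leave room for the tilt variance).
  Vigorous canopies thus give more acid, less sugar and lower pH, the
  agronomically expected direction.
- **Stream independence.** Each trait draws from its own seeded stream
  (`[seed, trait-index]`), so adding a trait or changing one trait's
  parameters never perturbs the others — a property the tests assert.

What passing tests on this field shows: the pipeline's operations are
correct, the estimators recover known generating parameters at realistic
noise, model selection prefers the true family, and conclusions survive a
resolution change. What it does not show: robustness to GPS dropouts and
multipath, to non-stationary spatial trends in soil or chemistry, to
season-to-season drift, or to the segmentation errors upstream of the vigor
percentages — none of which the generator emulates.

## Problem sizes and determinism

The test suite and acceptance checks run on the default field (219 samples,
~175 occupied 4 m cells, ~60 8 m cells), with 20-seed replication for the
model-selection frequency check and 50 random small designs for the
ANOVA/leave-one-out oracle comparisons; the full suite completes in a few
seconds. All randomness flows through explicit integer seeds: the generator
is bit-reproducible under a fixed seed, and property tests are seeded or
derandomized.

## Known limitations

- Ellipsoidal (not orthometric) heights; no map projections beyond local ENU.
- No spatial interpolation of empty cells by design; analyses use occupied
  cells only, which biases nothing but reduces n.
- The power family requires strictly positive predictor and response;
  zero-vigor cells cannot enter it (they are excluded with a domain error).
- ANOVA and t inference for the power family come from the nonlinear fit's
  Jacobian covariance and original-scale sums of squares; the exact
  SS decomposition identity holds only for linear-in-parameters families
  with an intercept.
- The qualitative normality ratings are a calibrated proxy for Q–Q
  linearity, not a hypothesis test; users wanting formal tests should apply
  one to the reported quantile pairs.
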