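# Methods

This note records the models behind `chemmap`, the parameters that matter,
what the synthetic data do and do not emulate, and the design choices made
where more than one defensible option existed. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The measurement problem

A fresh-cut pineapple slice is imaged by two line-scan reflectance sensors
(420–1000 nm and 1000–1600 nm), then ten cylindrical samples (18 mm cork
borer) are taken from fixed regions and assayed for moisture (MC, %),
soluble solids (SSC, %), titratable acidity (TA, g/100 mL citric acid) and
total carotenoids (CC, mg/100 g dry matter). The modelling task is to
predict those four quantities from reflectance at a handful of wavelengths
at which optical hardware is commercially available, and then to apply the
calibrated model to every pixel to obtain spatial distribution maps. The
compound fruit ripens fruitlet by fruitlet, so SSC and CC develop a
gradient along the stem axis — the scientific payoff of mapping rather
than averaging.

## Synthetic data generator

No dataset of this design is publicly deposited, so the generator is a
first-class component and defines the conditions under which everything
else is validated.

**Reference chemistry.** Six origins × 10 fruit × 10 regions (600 rows).
Per-origin means and SDs of the four compositions are fixed package
constants (`ORIGIN_STATS`); origin-level heterogeneity is substantial
(e.g. MC means 85.14–88.54 %). The joint distribution is a Gaussian
copula: a 4-variate standard normal with correlation matrix `R` is split
into a fruit-level random effect and a within-fruit residual (default
50/50 variance split — the partition is not identifiable from published
summaries, so it is exposed as configuration), then each margin is mapped
to a truncated normal (MC in (0, 100), the others non-negative) with the
origin's mean/SD.

The pooled CC–MC, CC–SSC and CC–TA Pearson correlations are calibrated to
−0.56, +0.52 and −0.14. Using those values directly as copula
correlations would *not* reproduce them in the pooled table: the pooled
covariance also carries the covariance of the six origin means, and the
truncated-normal transform attenuates the copula correlation. The
generator therefore solves, per pair, for the within-origin copula
correlation whose implied pooled Pearson correlation (computed by
Gauss–Hermite quadrature on the actual truncated margins, 32 nodes) equals
the target, using Brent root finding. The MC–SSC entry has no configured
target; it is completed with −0.30 (water and dry-matter solids are
compositionally complementary), which also keeps the completed matrix
positive definite — with an orthogonal completion the three calibrated CC
rows are jointly infeasible. If a user-supplied specification is non-PSD
it is rejected with the eigenvalue diagnostic; if *calibration* renders an
unusual design infeasible, the off-diagonal block is shrunk toward
independence with a warning.

**Chemistry fields.** Each fruit's slice is a disc on a raster (default
256×256 at 0.5 mm/px, so the 18 mm sampling discs are 36 px across). The
ten ROI centres sit on a 2 × 5 grid inside the disc; regions 1–5 run along
the stem axis. Each composition field is a low-order base surface
(optional axial/radial gradient, in composition units per normalised
coordinate) plus a Gaussian radial-basis correction anchored at the ten
ROI centres, with coefficients solved so that the *disc mean* over each
ROI equals the reference value to solver precision. This makes the
generator's tables and its images exactly consistent — the closed loop
the pipeline tests rely on.

**Optics.** Reflectance is linear in composition:
`R(λ) = baseline(λ) + Σ_b amp_b·G(λ; centre_b, width_b)·(c_b − ref_b)`,
clipped to [0, 1.2]. The default band set encodes the *sign structure*
of the reflectance–composition correlations a VIS/NIR study of yellow
flesh reports — MC positive near 490 nm and negative at the 960/1425 nm
water overtones, SSC negative near 488 nm and at the 1215/1240 nm
sugar/acid CH bands, TA weakly positive near 512 nm, CC strongly negative
near 507 nm (carotenoid absorption) — with amplitudes chosen so one SD of
each composition moves reflectance by 0.015–0.045 units. Magnitudes are
not fitted to any measured optical constants; only the signs and rough
scales are meaningful. Sensor frames are rendered as
`I = B + R·(W − B)` with additive Gaussian noise on the raw scene frame
(SD 1 % of white level, inflated ×5 outside 420–1600 nm to exercise edge
trimming); white/black frames are noise-free, standing for multi-scan
averaged references.

**Landmark scenes.** Three binding-head screws near the slice rim carry
the registration landmarks: the two endpoints of each ~5 mm head slit are
the six control points. The three *check* landmarks are placed on the rim
between the screws rather than at the slit midpoints: a slit midpoint is
the linear interpolant of its two control points, so errors there cannot
distinguish an affine from a projective fit; spatially independent check
points preserve the diagnostic role the check set exists for. Point
correspondences are exact under the true transform plus isotropic
Gaussian jitter (default 0.5 px) on the distorted frame.

**What the generator does not emulate:** illumination non-uniformity and
BRDF/scattering effects, rind or crown morphology, spatially correlated
sensor noise, wet-chemistry measurement error, and any non-linearity of
the reflectance–composition relation. Tests passing on these data show
the *procedures* are implemented correctly and recover planted structure;
they do not certify field performance on real fruit, where correlations
in the 0.5–0.6 range rather than 0.95+ are typical.

## Preprocessing

Calibration follows `R = (I − B)/(W − B)` per band; negatives are clipped
to zero and counted, values above 1 are preserved and counted (white
references are imperfect). A band where `W − B ≤ 0` anywhere aborts with
the band named. Savitzky–Golay smoothing defaults to an 11-point (55 nm)
window, order 2 — wide enough to suppress shot noise, narrow enough to
preserve 30–50 nm absorption features — with mirror padding so the length
is unchanged. Fusion is a hard switch at 1000 nm: grid points below come
from the visible sensor (linear interpolation), at or above from the NIR
sensor; in the physical 860–1000 nm overlap the visible sensor wins. No
multiplicative matching across the seam is applied by default (the
operation is a plain integration of two ranges); a ratio-matching flag
exists but is off.

## Registration

Coordinates are 0-based pixel centres, x = column, y = row; transforms map
the distorted (photograph) frame to the reference (hypercube) frame.
Similarity and affine fits are exact least squares; the projective fit
refines the normalised-DLT solution with a geometric Levenberg–Marquardt
polish and, when over-determined, never returns a worse control-point
optimum than the nested affine fit — this enforces the monotonicity
`RMSE(similarity) ≥ RMSE(affine) ≥ RMSE(projective)` on control points.
Error conventions (not uniquely determined by the usual formulas when
applied to 2-D points, so fixed here): RMSE pools squared *Euclidean
point distances*; MAPE pools *per-coordinate* absolute percentage errors.
Family selection is argmin of check-point RMSE, ties broken by check-point
MAPE, then by fewer required control points. Circle extraction is a
Canny + circular-Hough accumulator (1 px radius resolution, non-maximum
suppression at the minimum radius); ROI masks label discs 1–10 by centre
distance after mapping centres through the chosen transform, clipping at
image edges and refusing overlapping discs.

## Wavelength selection

Candidates are first restricted to the 5 nm availability grid
(420–1600 nm, 237 points) with the requested modality flag; `filter` uses
the bandpass-filter list, `light_source` the union of LED and laser lists.

*RReliefF* (regression Relief): for each probed instance the ten nearest
neighbours by Manhattan distance on range-normalised features contribute,
with rank-exponential weights (σ = 20), to estimates of P(target differs),
P(feature differs) and their joint; the feature weight is
`P(dA|dC)−P(dA|¬dC)`. All instances are probed in order, making the
weights deterministic and sample-order invariant; constant features score
exactly zero and a constant target is an error. *Pruning* implements the
stated loop literally: take the top 20 by rank, keep the rank-1 candidate,
repeatedly drop later candidates with |Pearson r| > 0.8 against the
current survivor, advance, truncate to six. Absolute correlation is used
(the threshold is quoted unsigned).

*CFS*: subset merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` with mean absolute
feature–target and feature–feature correlations; zero-variance features
are treated as uncorrelated with a warning. The best-first search starts
from the empty set, expands by single add/remove toggles, orders nodes by
merit, and stops after five consecutive expansions without a new best
merit. A winner larger than six members is reduced by evaluating all
six-member sub-subsets (ties resolved to the lexicographically smallest
wavelength list). The merit itself is also used as "the correlation of a
subset with the composition" wherever a subset-level score is needed —
the phrase is not otherwise operational.

## Calibration models

Partitioning holds out two whole fruit per origin (all ten ROIs each;
120 rows at study scale) for validation, then shuffles the remaining rows
into calibration (65 % of the total, 390) and cross-validation (15 %, 90).
The fractions are of the *total* row count — that is the only reading
under which the three sizes are mutually consistent — and designs whose
arithmetic cannot exhaust the remainder are rejected rather than silently
rounded.

The network is 1 hidden layer × 4 tanh neurons, linear output; inputs and
target are z-scored on the calibration split only, predictions returned in
original units. Training is full-batch Levenberg–Marquardt with analytic
Jacobian and adaptive damping (×10 on reject, ×0.1 on accept); one epoch
is one accepted step. Stopping: standardised training MSE ≤ 1e-4, or 500
epochs, or 15 epochs without a new cross-validation error minimum (the
best-cross-validation weights are restored), or an unimprovable step. The
early-stopping monitor is the cross-validation split. A learning rate of
0.3 is stored for configuration fidelity with the classic toolbox
convention even though LM uses damping, and the stopping record names the
optimizer. Twenty replicate trainings per candidate wavelength set are
summarised as mean ± SD of R/RMSE/MAPE per stage; the winner has the
highest mean cross-validation R (ties: lower cross-validation RMSE, then
MAPE), and its best replicate is validated on the held-out fruit.

## Mapping and evaluation

Cubes are flattened pixels × bands (row-major, invertible); the foreground
mask is a fixed threshold or Otsu (with 3-class Otsu and mid-class
selection when bright fiducials must be excluded); background pixels carry
NaN in arrays and 0 plus an explicit mask in exported images, so genuine
zero predictions are never conflated with background. Region-wise
reliability is |ROI-mean prediction − reference|/reference × 100 per
validation fruit and region, compared across the ten regions by one-way
ANOVA followed by Tukey HSD (α = 0.05) with a maximal-clique compact
letter display; a non-significant ANOVA short-circuits to a single letter.
Histogram statistics are moments over foreground pixels; kurtosis uses the
non-excess convention (normal = 3), recorded in the output; zero-variance
maps report flagged zeros.

## Pipeline and problem sizes

The `chemmap run` pipeline derives one seed per stage from the root seed
(CRC-32 of the stage name), so any stage is individually replayable, and
partitions *before* selection: the validation fruit never reach wavelength
selection or training (the test suite corrupts their spectra and asserts
byte-identical selections and weights). The demo configuration uses
128×128 rasters at 1 mm/px, two rendered validation fruit, three training
replicates and 120 epochs so a full run takes seconds; the study-scale
configuration (256×256 at 0.5 mm/px, 20 replicates, 500 epochs) is the
default for real use. The acceptance script scales its experiments to run
in about a minute: 200 registration scenes, 100 search datasets, 50
recovery seeds, 500 Tukey simulations, a 6 000-row correlation table —
sizes chosen so each rate estimate has a standard error comfortably inside
the margin it is compared against.

## Known limitations

- The optics model is linear and band-additive; real reflectance saturates
  and scatters, so amplitude parameters are not interpretable as
  absorption coefficients.
- The wavelength-recovery experiment uses spectrally resolvable 8 nm bands
  and statistically independent compositions; with broad overlapping bands
  and correlated chemistry the *information* optimum genuinely sits on
  band flanks, and no selector should be expected to return band centres.
- Tukey letters from only two mapped fruit (demo scale) have little power;
  the grouping is meaningful at the study's twelve validation fruit.
- `RReliefF` is O(n²·d) per run; at 600 × 237 this is fractions of a
  second, but very large tables would need subsampled iterations
  (`n_iterations`), which introduces seed dependence.
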