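# Methods

`threemic` models and quantifies one phenomenon: tumor cells in the ischemic
interior of a 3D culture become dispersive — they migrate persistently, degrade
the surrounding extracellular matrix (ECM), and lose epithelial adhesion — while
well-nurtured cells at the nutrient-exposed side stay cohesive and rounded. The
experimental geometry throughout is a chamber open to fresh medium on one side,
in which a dense "consumer" cell monolayer generates one-dimensional gradients of
oxygen, nutrients, and acidity over embedded tumor spheroids; every profile in
the package is therefore a function of distance (mm) from that opening, with
`proximal` ≤ 2 mm, `distal` > 8 mm, and `intermediate` in between.

## Spheroid morphometry

**Invasiveness index.** The shape readout is the spheroid perimeter divided by
the perimeter of the circle of equal area, `P / (2√(πA))` — the reciprocal of
circularity. It is exactly 1 for a disk and grows with boundary ruffling.
Perimeter and area come from the same sub-pixel contour: the binary mask is
smoothed with a 1-pixel Gaussian and the 0.5-level marching-squares contour is
measured (arc length and shoelace area). The smoothing matters: marching squares
on a raw binary image overestimates a disk's perimeter by ~5.4% (staircase
bias), which would already exceed the 2% tolerance we claim for the circle
identity; after smoothing the residual bias is ≤0.5% against dense-polygon
oracles. Pixel-edge counting is worse still (~27% high on disks) and is not
used. Objects under 16 foreground pixels are rejected: contour estimates below
that size are unstable. The index is invariant to translation, rotation, and
uniform scaling within the stated 2%.

**Fluorescence ratios.** Per-spheroid reporter quantification (hypoxia reporter
over a constitutive membrane label; cleaved-collagen signal over the same label)
is the ratio of channel means over the mask, each background-subtracted with
the median over background pixels. The median is a deliberate robustness
choice; the mean (not integrated) intensity is used, an assumption flagged
because either convention is common.

**Local density.** Cell density is read from nuclei positions via Delaunay
triangulation: the local density is the inverse area of each triangle, and the
per-image summary is the mean of those inverse areas. Dispersal shows as a
monotone decay of the summary over frames; pure radial expansion by factor `s`
per frame decays exactly as `s^(−2t)`, which the tests exploit as an oracle.
Collinear or <3-point inputs raise a geometry error rather than returning
degenerate triangles.

**ECM degradation.** For gelatin-type assays (degradation = local loss of
fluorescence), the score is the fraction of mask pixels whose sample intensity
falls below a threshold fraction (default 0.5, configurable) of the
co-registered reference intensity at the same pixel. For quenched-collagen
assays (degradation = gain of cleaved-collagen fluorescence), the score is a
fluorescence ratio as above.

**pH ratiometry.** Extracellular pH is estimated from the green/blue ratio of
phenol-red-containing medium. Calibration anchors (ratio, pH) measured on
titrated medium are interpolated with a monotone piecewise cubic (PCHIP);
anchors must be strictly monotone in ratio, queries outside the calibrated
range are clamped to the terminal anchors and counted in the profile's flags.
Images are pooled into 0.5 mm distance bins (configurable) before ratioing.

**Drug-gradient estimation.** A fluorophore-conjugated drug analog stains its
target in proportion to local drug level, so concentration is estimated as
`c(d) = c0 · I(d)/I(0)` with `c0` the applied source concentration. The
estimate is linear in `c0` and invariant to intensity units. If noise breaks
monotonicity, the profile is projected onto the nearest non-increasing sequence
(isotonic regression) and flagged. With the decay length anchored so relative
intensity is 0.30 at 10 mm, a 150 nM source gives 45 nM there.

**Fits and statistics.** Metric-vs-distance relations are summarized with
ordinary least squares plus Pearson's r; two-condition contrasts use two-tailed
t tests, three or more use one-way ANOVA followed by Tukey–Kramer.

## Track statistics

Tracks are time-ordered (t, x, y) samples in minutes and μm, nominally at
uniform cadence; the reference cadence is 15-min frames over 24 h (96 frames).
Per-track scalars: instantaneous speeds (finite differences), net displacement,
path length, and persistence = net/path (1 for straight motion, 0 for a closed
loop; NaN for a track that never moved). A *runner* is a track whose net
displacement reaches 50 μm; the rule is inclusive (≥), with a strict-inequality
flag, because the two available wordings of the threshold differ and the
figure-legend wording ("50 μm or more") is the operational one. Tracks missing
more than 10% of expected frames are excluded from MSD pooling; tracks shorter
than 6 frames are excluded from exponent fitting but kept in displacement
statistics.

**MSD and exponent.** The default estimator is the time-averaged MSD pooled
over tracks: squared displacements averaged over all start times and all
tracks, with lags capped at one quarter of the track duration (longer-lag
time averages are dominated by noise). An ensemble (fixed-origin) estimator is
also provided. The exponent is the least-squares slope of log MSD vs log lag
over the first quarter of the curve's lags, requiring ≥5 lags with ≥20
displacement pairs each; 1 is a random walk, 2 ballistic motion. Confidence
intervals come from a percentile bootstrap over tracks (resampling tracks,
recombining their per-track displacement sums); an ensemble is called
*superdiffusive* when the CI lies entirely above 1. The 80% bootstrap CI covers
the random-walk exponent at close to nominal rate on brownian fixtures (checked
at 200 replicates).

**Directionality.** Final-displacement vectors are measured relative to the
chamber-opening direction (toward nutrients; −x in image coordinates by
default, configurable). The Rayleigh test uses Z = n·R̄² with the standard
small-sample series correction of the p-value (adequate for the per-spheroid
track counts here, n < 50); when displacement magnitudes are supplied, Moore's
rank-weighted statistic R* is also computed with a seeded Monte Carlo null
(uniform angles, 9999 draws by default).

## Cellular Potts model

Cells are spin domains on a square lattice with a Graner–Glazier Hamiltonian:
contact energy `J(τᵢ,τⱼ)` summed over unlike-spin neighbor pairs (2nd-order
Moore neighborhood, which reduces lattice anisotropy) plus a quadratic volume
constraint `λ Σ (v − V_T)²`. Types are ECM/medium (M, spin 0, one compartment,
no volume constraint), ischemic *core* cells (C1), and well-nurtured *cortical*
cells (C2), assigned by initial position: the initial cluster is a disk
partitioned into contiguous equal-volume cells (a power-diagram balancing of a
sunflower-spiral seeding; plain Voronoi rim cells deviate by ±40% from the
target volume, the balanced partition stays within ±8%), with the innermost
fraction of cells typed C1.

**Kinetics.** One Monte Carlo step is one copy attempt: a random boundary
(target, source-neighbor) site pair — drawn by rejection until the two spins
differ — with the source spin copied into the target under Metropolis
acceptance `min(1, exp(−ΔE/T))`; at T = 0 only strictly downhill moves are
accepted. A sweep-based accounting (lattice-size attempts per step) is
available by flag. ΔE is computed locally and verified in tests against global
Hamiltonian recomputation on every audited move. The kinetic loop is compiled
with numba; runs are bit-reproducible per seed. Boundaries are fixed (no
wrap): border sites never change, acting as a hard wall. A dispersing cell
that reaches the wall no longer aborts the run — at desk scale strong
dispersal does reach the wall in a minority of runs — but is recorded in
`CPMResult.border_contact`, since that cell's subsequent displacements are
reflected. Cell connectivity is not enforced (simplest Potts dynamics).

**Conditions.** The biology enters as inequalities on J. Reduced epithelial
adhesion in ischemic cells: `J_C1C1 > J_C1C2 > J_C2C2` (core–core contacts
least stable). Increased ECM affinity of ischemic cells: `J_C1M < J_C2M`. Four
presets apply neither rule (`baseline`, fully symmetric), one rule each
(`low_adhesion`, `invasion`), or both (`combined`). Only the inequalities are
mechanistic claims; the absolute values are implementation choices, frozen at:

| preset | J_C1C1 | J_C1C2 | J_C2C2 | J_C1M | J_C2M |
|---|---|---|---|---|---|
| baseline | 8 | 8 | 8 | 16 | 16 |
| low_adhesion | 20 | 10 | 6 | 16 | 16 |
| invasion | 8 | 8 | 8 | 4 | 16 |
| combined | 30 | 20 | 6 | 4 | 16 |

with T = 9, λ = 2, V_T = 60 sites, core fraction 0.5 globally. Two structural
relations in the combined preset matter more than the numbers. First,
`J_C1C2 > (J_C1C1 + J_C2C2)/2`: heterotypic contacts are *not* favored over
the mean, so the core cannot relax by intermingling — its only relaxation
channel is outward expulsion. Second, `J_C1C2 ≈ J_C1M + J_C2M`: a detached
core cell gains nothing by re-adhering to the cortex, so expulsion is not
undone and dispersal is sustained through the run. In the low_adhesion preset
the opposite choice (`J_C1C2` below the mixing threshold) makes the
populations intermingle while `J_CM = 16` keeps everyone clustered. The
qualitative dispersal ordering is robust to ±25% rescaling of the whole J
table (tested).

At the published scale the lattice is 200×200 with 100 cells and 1.28×10⁸
copy attempts. The desk-scale preset used by the tests and the acceptance
analysis is 100×100 with 25 cells and 2×10⁶ attempts, snapshots every 2×10⁴
attempts (101 snapshots) — chosen to preserve the qualitative outcomes while
running in a few seconds.

**Metrics.** The mixing index is the fraction of cell–cell contacts that are
heterotypic, divided by the expectation under random assignment of the type
labels to cells (2·n₁·n₂/(n(n−1)) over live cells): ~1 for randomly arranged
types, <1 for sorted layouts, >1 for alternating ones. The ECM-invasion
fraction is the fraction of each type's volume outside the initial cluster
footprint dilated by 2 sites (so boundary jitter does not count). Centroid
tracks (one sample per snapshot, time in snapshot units — exponents are
invariant to the time unit) feed the track-statistics module; the per-type MSD
exponent is fitted on tracks pooled across replicate runs, mirroring how
experimental analyses pool cells across spheroids, because the onset time of
dispersal in a 25-cell system varies strongly between seeds. A fit is refused
when maximal MSD is below a quarter site² (frozen dynamics carry no kinetics).

**Behavior at the frozen parameters** (desk scale, means over 10 seeds, as
computed by the test suite): baseline neither mixes (0.74) nor invades
(0.00); low_adhesion mixes (1.52) without invading (0.04); invasion alone
invades moderately (0.04) without sorting-driven mixing; combined expels the
core into the ECM (0.44) with pooled core-cell exponent ≈ 1.05–1.11 and
bootstrap CI above 1 — dispersal emerges although the model contains no
directional cue. Two desk-scale limits are worth stating plainly: (i)
baseline centroid motion is *sub*diffusive (pooled exponent ≈ 0.74), not
random-walk-like — cohesive clusters cage their cells and membrane
fluctuations are anti-persistent at short lags; (ii) because sustained
superdiffusive dispersal requires expelled cells not to re-adhere, the
combined condition's final-state mixing index is *low* (most core cells have
left the cluster) — its intermingling is transient, en route. Both are
properties of the small system, not bugs; parameterizations that favor
persistent mixing produce re-adhesion and subdiffusive cores.

## Synthetic data

All inputs are generated, seeded, and bit-reproducible; identical spec + seed
gives identical output, and every writer can attach a JSON sidecar with the
generating spec.

- **Spheroid masks**: star-convex boundaries `r(θ) = R(1 + A·S(θ))` with
  `S(θ)` the mean of sinusoids over chosen angular modes with seeded random
  phases; `A < 1` guarantees a simple boundary. Amplitude 0 is a disk;
  raising it emulates the ruffled, protrusive ischemic morphology.
- **Nuclei clouds**: a regular grid jittered by Gaussian noise (dispersion in
  μm), at least 3 points.
- **Tracks**: brownian (i.i.d. Gaussian steps), ballistic (fixed random
  heading), persistent (constant speed, heading decorrelating as
  `exp(−dt/P)` — the discrete correlated walk, whose ensemble MSD has the
  exact closed form used as an oracle in the tests, with the Fürth-type
  crossover from ballistic to diffusive at lag ~P), and biased (brownian plus
  constant drift). Defaults: 15-min cadence, 96 steps, RMS step 2 μm.
- **Gradient images**: a flat denominator channel and a numerator equal to
  denominator × profile, repeated along the short axis (the chamber gradient
  is one-dimensional), plus independent Gaussian read noise; 10 px/mm by
  default.
- **Decay profiles**: exponential `c0·exp(−d/L)`.

What the generators do *not* emulate: segmentation and tracking errors,
photobleaching, uneven illumination, cell division and death, 3D structure,
and spatially correlated noise. Passing tests therefore validate the
estimators and the simulation — not robustness to those artifacts.

## Numerical choices and degenerate inputs

Ratios with non-positive denominators after background subtraction, empty
masks, zero source intensity, collinear point sets, non-monotone calibration
anchors, non-increasing track times, unknown model/condition/scenario names,
and schema violations in CSV/TIFF inputs all raise typed errors
(`threemic.errors`) rather than returning silent values. Scenario runs write a
manifest (config, seed, package version) sufficient to reproduce every
artifact byte-for-byte; a single global seed fans out to per-module streams
via seed sequences keyed by (seed, stream).

## Known limitations

- The Potts model has no chemotaxis, division, death, 3D lattice, or enforced
  cell connectivity; ECM and medium are one compartment.
- Desk-scale results quantify a 25-cell system; the bimodality of dispersal
  onset and the subdiffusive baseline discussed above soften at larger scale.
- pH estimation assumes the calibration medium matches the imaged medium;
  the monotone interpolant is a modeling choice, not a fitted titration curve.
- Track statistics assume 2D positions; z-motion in thick samples is ignored.
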