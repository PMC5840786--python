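# Methods

## The procedure

`conjmap` quantifies directional spatial overlap between two signed
voxel-wise Z-maps on a common grid. The core statistic and decision rule:

1. **Threshold grid.** 500 one-tailed voxel-level p cutoffs from 0.05 to
   0.0001 in steps of 0.0001, each converted to a Z cutoff via the upper
   standard-normal quantile (so the display threshold Z ≥ 2.58 corresponds
   to one-tailed p ≈ 0.005). A two-tailed conversion is available as a
   config switch (`tail="two_tailed"`), but the default is one-tailed
   because every contrast in the four-scenario table is directional.
2. **Directional conjunction.** For a scenario with directions
   (s_A, s_B) ∈ {+, −}², the suprathreshold masks are {s_A·Z_A ≥ z} and
   {s_B·Z_B ≥ z} within the shared mask (intersection of the two input
   masks, computed once). Overlap percent is the mean of the two per-map
   intersection proportions, defined as 0 when either mask is empty so
   curves stay well-defined at stringent thresholds. No cluster-extent
   filtering enters the statistic anywhere.
3. **Smoothness matching.** Per-axis FWHM of each observed map from the
   classic Gaussian-field estimator on within-mask first differences,
   FWHM = d·√(−2 ln 2 / ln ρ) with ρ = 1 − msd/(2σ²); axes with ρ ≤ 0 are
   reported below-resolution; the per-map summary is the geometric mean of
   defined axes and the simulation target is the arithmetic mean of the two
   maps. The spatial-autocorrelation-function (long-tailed) smoothness model
   used by newer estimators is intentionally not implemented; the null
   fields here are exactly Gaussian, matching the generator.
4. **Monte Carlo null.** Each iteration draws two independent white-noise
   fields on the full grid, smooths them to the target FWHM, re-standardizes
   within the mask, and records the overlap curve. One shared null serves
   all four scenarios because the simulated fields are sign-symmetric;
   a per-scenario mode is available for asymmetric use cases
   (`permutation_null`, which shuffles group labels and refits both GLMs).
   Percentile bands (0.5th, 50th, 99.5th) use the linear-interpolation
   empirical quantile; the definition is recorded in output metadata.
   Full-scale default is 5000 iterations; the desk-scale profile used in
   tests and the acceptance script is 500 iterations on a 32³ grid.
5. **Decision.** A scenario is significant when its observed curve is
   *strictly above* the 99.5th band at ≥ ceil(0.70·n) thresholds (350 of
   500). Strict comparison breaks ties conservatively: at very stringent
   thresholds both observed and null overlaps are frequently exactly 0, and
   counting ties as exceedances would inflate the count.

## Upstream stages

**Derivatives.** Five voxel-wise resting-state derivatives are computed from
4D series: ReHo (Kendall's W over the 7/19/27-voxel neighborhood, with the
standard tie correction; computed on ranks of the raw series), VMHC (Pearson
correlation with the left-right mirrored voxel, Fisher-z), degree centrality
(count or Fisher-z-weighted sum of correlations above r = 0.25 with all other
in-mask voxels, chunked above a voxel budget so the full correlation matrix
is never materialized), fALFF (amplitude fraction in 0.01–0.1 Hz of the full
positive-frequency amplitude after linear detrending), and seed iFC (Fisher-z
correlation with a mean seed series). Defaults that the underlying studies
leave to convention — the DC threshold/mode, the fALFF band, the seed
geometry — are explicit `MetricConfig` fields recorded in provenance.
Correlational/spectral metrics detrend first (quadratic optional); Fisher-z
is clipped at |r| = 1 − 1e−7 so outputs stay finite. Maps are smoothed
*after* computation (6 mm FWHM default); smoothing the input series would
inflate ReHo's local concordance.

**Group GLM.** One OLS fit per voxel with covariates intercept, group
indicator, centered age, reference-coded site dummies, mean framewise
displacement, and the subject's within-mask map mean. Site enters as fixed
dummies (the alternative — random site effects — is out of scope; a
single-level group GLM matches the procedure being modeled). The group t is
converted to Z by probability matching through log-space survival functions
(`t.logsf` → `ndtri_exp`), which stays finite and monotone far into the
tails. Zero-residual-variance voxels get Z = 0 and are counted in a log
message.

## Synthetic data: what it emulates and what it does not

The generators provide every input the pipeline needs, as pure functions of
spec + seed (one `SeedSequence` fanned out in a fixed documented order).

* **Smooth Z-fields** — white Gaussian noise smoothed on the full grid
  (masking first would distort edge smoothness), then re-standardized within
  the mask. Requested FWHM between 1× and 4× voxel size is recovered by the
  independent estimator within 10%.
* **Planted pairs** — isotropic Gaussian bumps (σ = radius/2, truncated at
  3σ) added to both standardized fields with the sign pair fixed by the
  scenario, so the peak added Z equals the requested amplitude and the
  ground-truth voxel set (the radius sphere) is recorded. Defaults for the
  recovery studies (peak |Z| = 6, radius 4 voxels) are chosen for
  testability: real effect amplitudes/extents are unknown, and nothing here
  claims realism for them.
* **Cohorts** — per-subject unit-variance white noise (optional AR(1)) plus
  two structured components: a brain-wide per-subject component (amplitude
  γ ~ N(0.3, 0.1), group-independent) that gives the within-mask map mean
  its between-subject variability — the role the map-mean nuisance covariate
  plays in real cohorts — and a regional effect-carrying component (base
  amplitude α ~ N(0.5, 0.15)) shaped per metric: an in-band 0.05 Hz tone for
  fALFF, a shared regional series for ReHo, mirrored for VMHC, coupled to a
  fixed 10% scatter set for DC, and seed-locked for seed iFC. The requested
  `effect_size` is defined in within-group voxel-wise SD units of the
  *derivative*; since no closed form maps amplitude to each derivative, the
  generator calibrates empirically on the cohort's own noise (measure the
  within-group SD and the derivative-vs-amplitude slope with a probe
  amplitude, then solve for the case-group shift). The mapping is locally
  linear but mildly concave, so realized effects land slightly below the
  request (≈1.4 for a requested 1.5) — well within what the recovery checks
  require. Covariates (age, site, mean FD) are generated independently of
  group unless a confound is explicitly configured.

  Not emulated: hemodynamics, physiological noise, motion artifacts, spatial
  noise correlations within subjects, surface geometry. Passing tests
  therefore show the *statistics* are correctly calibrated for
  exchangeable-noise cohorts, not that the pipeline is robust to structured
  artifacts of real acquisitions.
* **Atlases** — Voronoi tessellation of the mask around random in-mask
  seeds, with stray fragments merged into an adjacent label so every label
  region is 26-connected. A stand-in for published parcellations; real atlas
  volumes are accepted as user inputs.

## Numerical choices

* Overlap curves are computed by sorting the two in-mask value vectors and
  the voxel-wise minimum once per scenario and binary-searching all 500
  cutoffs — exactly equal (tested) to the per-threshold boolean-mask loop,
  at O((V + T) log V).
* Grid compatibility requires equal shapes and affines within 1e−4; no
  implicit resampling, ever. NaN voxels are moved outside the mask and
  reported.
* Voxel coordinates are 0-based indices; world coordinates via the NIfTI
  affine (RAS+).
* The threshold-grid constructor verifies that the p range is an integer
  multiple of the step (tolerance 1e−6 in step units).
* Constant time series (rank- or correlation-undefined) produce 0 and are
  counted; a constant seed series is an error.

## Problem sizes

Tests and the acceptance script run desk-scale profiles chosen so the whole
suite completes in minutes on one CPU: 32³ grids (ellipsoid mask ≈ 14k
voxels) with 500-iteration nulls for calibration/recovery studies, 200
decision replicates for false-positive rates, 20 replicates per scenario for
recovery, 16³ × 64 cohorts with 20 subjects per group for GLM studies, and
≤ 16³ fixtures for the exact brute-force metric comparisons. The full-scale
profile (MNI-like grids, 5000 iterations) is reachable through the same
APIs.

## Known limitations

* The classic first-difference FWHM estimator is mildly biased at high
  smoothness relative to grid size; the 10% recovery tolerance reflects it.
* Under the global null at desk scale, the mean per-threshold exceedance of
  the 99.5th band sits slightly below the nominal 0.5% (≈0.3–0.4%): at
  stringent thresholds overlap is exactly 0 for almost all draws, and strict
  tie-breaking makes those thresholds conservative. This conservatism is
  inherited by design, not corrected away.
* The permutation null permutes group labels and refits both GLMs; what the
  original procedure permuted is not specified in the source material for
  this implementation and label permutation is the documented
  interpretation.
* Network attribution percentages are taken over atlas-covered voxels, with
  mask voxels outside atlas coverage reported separately as "unassigned" —
  the denominator choice is explicit rather than hidden.
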