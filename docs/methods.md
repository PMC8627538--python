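# Methods

This note documents the models and conventions behind `petsil`: what each
stage computes, the defaults and why, what the synthetic cohorts emulate and
what they deliberately do not.

## Radiomic feature extraction

Each lesion is a (volume, binary mask) pair on an isotropic grid. The
extraction chain is resample → discretize → feature families.

**Resampling.** Trilinear interpolation for the volume, nearest-neighbour
for the mask, onto an isotropic grid (default 2 mm — typical PET radiomics
practice; configurable). Grids share the origin at the first voxel centre.
An input already at the target spacing is passed through untouched.

**Discretization.** In-mask SUVs map to grey levels `1..n_bins` via
`1 + floor(n_bins·(x − lo)/(hi − lo))`, clamped to `n_bins` at the top
bound. Default: relative min–max bounds with `n_bins = 64` (a common PET
default; relative mode never produces empty VOI ranges on synthetic data).
Absolute fixed-SUV bounds are available (`ABSOLUTE_BOUNDS`, values clamped).
A constant VOI maps wholly to level 1. Raising a voxel's SUV can never
lower its own level (monotonicity, property-tested).

**Roster (42 features).** Shape 2 (`Volume_mL`, `Sphericity`) + first-order
9 + GLCM 6 + GLRLM 11 + NGLDM 3 + GLZLM 11. The roster is configurable
(order and subset), so an alternative 42-name list can be swapped in; the
default order is frozen in `DEFAULT_ROSTER`.

- *First order*: min/mean/std/max and standardized third/fourth moments on
  the raw SUVs (population normalisation; kurtosis is non-excess). Energy,
  Entropy (log₂) and Uniformity are computed on the discretized histogram;
  note Energy and Uniformity are both Σp² under this naming convention and
  therefore coincide. Zero-variance VOIs report Skewness = Kurtosis = 0
  with a degenerate flag.
- *Shape*: volume is voxel count × voxel volume (mL). Sphericity is
  `π^(1/3)(6V)^(2/3)/A` with `A` from a marching-cubes isosurface of the
  mask. The mask is pre-smoothed with a half-voxel Gaussian before meshing:
  meshing the raw binary mask overestimates curved areas by up to ~9%
  (45° facets), which would push a digitized ball's sphericity down to
  ~0.91; with smoothing a radius-10 ball scores ~0.96 and a 20-voxel cube
  is within 5% of its closed form. Masks too thin to mesh fall back to the
  exposed voxel-face area.
- *GLCM*: co-occurrences at Chebyshev distance 1 accumulated over the 13
  unique 3-D directions and both orientations into one symmetric matrix
  normalized to sum 1 (accumulate-then-normalize, not per-direction
  averaging). Correlation is defined as 0 when a marginal variance is 0;
  `0·log 0 := 0` throughout.
- *GLRLM*: runs are maximal same-level straight segments within the mask,
  accumulated over the 13 directions; run percentage is
  `n_runs/(n_voxels·n_directions)`. Conservation (`Σ length×count` equals
  the voxel count per direction) is property-tested.
- *NGLDM*: the 26-neighbourhood grey-level difference construction —
  per-voxel `|level − mean(in-mask neighbour levels)|` accumulated per grey
  level — yielding Coarseness, Contrast, Busyness. Conventions: Contrast is
  0 when only one grey level is present, Busyness is 0 on a zero
  denominator, Coarseness is capped at 10⁶ (constant VOIs).
- *GLZLM*: zones are 26-connected components of constant grey level; zone
  percentage is `n_zones/n_voxels`; zone sizes partition the voxel set
  (property-tested).

All 42 features are finite on every non-degenerate VOI, and the
direction-aggregated texture families are exactly invariant to axis-aligned
90° rotations (both property-tested).

## Similarity analysis

**Embedding.** Default: per-feature z-score over all lesions in the analysis
set (zero-variance features are dropped and listed, never divided by zero),
Euclidean distance — the simplest space in which the silhouette is
well-defined. Optional PCA projection (`ZSCORE_PCA`, fixed dimension or 90%
retained variance) is provided for users who prefer a low-rank latent space;
both are reported so results can be matched against either convention.

**Silhouette with patients as clusters.** `s(i) = (b−a)/max(a,b)`; lesions
of single-lesion patients receive 0 and an `excluded` flag — they are left
out of every mean but still act as neighbour clusters when computing `b` for
other lesions (this matches the common library convention, which is also why
an independent cross-check against `sklearn.metrics.silhouette_samples`
agrees to 1e-12 in the tests; the implementation itself is independent and
is additionally checked against a brute-force O(n²) oracle). When
`a = b = 0` (coincident duplicates across patients) the value is 0.

**Slicings.** Anatomy-based: restrict to one site class, *re-embed on the
subset*, recompute — each slicing is an independent analysis, so
standardization is recomputed on the subset rather than inherited. The same
for metabolism-based slicing, with tertile boundaries at the inclusive
empirical 1/3 and 2/3 quantiles of the whole cohort's lesion SUVmax;
boundary ties go to the lower tertile (deterministic and
order-independent — with all SUVs equal, every lesion lands in tertile 1).
Cohort means average per-patient means over non-excluded patients (the
per-patient convention; a per-lesion average is a one-line change).

**Paired slicing comparison.** Classical two-sided paired t-test on
per-patient means, pairing on patient id over patients non-excluded in both
slicings. Degenerate cases are explicit: all-zero differences give
`t = 0, p = 1`; constant nonzero differences give `p = NaN` with a flag.

## Burden classification and group tests

Oligometastatic: lesion count at or below the threshold (3 or 5), inclusive
by default; the exclusive (`n < t`) convention — which some summary tables
use — is available behind a flag, since the two appear interchangeably in
clinical writing. The three-way class (≤3 / between / >5-threshold) is
derived consistently, and the nesting invariant (oligo-by-3 implies
oligo-by-5) is asserted on every cohort.

The univariate screen runs a two-tailed Mann–Whitney test per feature across
a two-group split, by default on lesion rows labelled with their patient's
group (per-patient medians are available). Default significance levels:
0.01 for the Gleason split, 0.001 for all other categories; PSA is tested
separately at 0.05 with the same statistic — chosen because PSA is heavily
right-skewed, which rules out t-tests. No multiple-testing correction is
applied by default (an optional Benjamini–Hochberg column can be switched
on). Kruskal–Wallis (tie-corrected, chi-square p) compares per-patient
silhouette means across splits after dropping excluded patients. The PSA
median split uses the analysed cohort's own median, not any fixed external
value.

## Clustering

k-means (20 seeded restarts per k) over a k range, keeping the k with the
highest mean silhouette — an explicit, reproducible operationalisation of
picking the "best interpretable" solution; Ward agglomerative clustering is
available behind a flag. A cohort of identical points yields a flagged
degenerate single-cluster solution rather than an arbitrary split. Clusters
are profiled by their composition over SUVmax tertiles, burden classes and
site classes, with enrichment flags (cluster proportion above cohort
proportion) and a descriptive chi-square test.

## Synthetic cohorts

The generator emulates the *shape* of a recurrent prostate-cancer PET
cohort, not any particular patient data set:

- 92 patients by default; lesion counts from a categorical law with ~40%
  single-lesion patients, mean ≈ 4 lesions/patient, tail to 20 (the
  per-patient count distribution of real cohorts is rarely published, so
  this law is a free, documented choice).
- site probabilities ≈ (0.18, 0.22, 0.60) for regional LN / distant LN /
  bone; per-site lognormal SUVmax (bone hotter).
- each patient draws a phenotype archetype (private when
  `n_archetypes ≥ n_patients`, shared otherwise); lesion features =
  archetype mean + site-specific shift + within-patient noise. Cohesion is
  monotone in `sigma_within/sigma_between` by construction, which is all the
  silhouette analysis requires of it.
- within-patient noise is Gaussian with an optional shared latent factor
  (`metabolic_factor_weight`, default 0.3): real radiomic features are
  strongly inter-correlated and largely track lesion intensity, so a purely
  spherical noise model (weight 0) would make SUV-restricted slicings
  almost no more cohesive than the full analysis — one latent factor,
  with log-SUVmax coupled to the factor score
  (`suv_phenotype_coupling`, default 0.8), reproduces the qualitative
  behaviour of SUV-homogeneous lesion subsets. Per-axis noise variance
  stays `sigma_within²` either way.
- optional couplings: `sigma_within_slope` grows within-patient dispersion
  with lesion count (high-burden patients carry more heterogeneous
  lesions); `psa_burden_coupling` (default 0.6) raises log-PSA with log
  lesion count.
- volume mode gives each archetype a texture law (mean SUV, field s.d.,
  correlation length) and synthesizes each lesion as a clipped correlated
  Gaussian random field inside an ellipsoidal mask, background near zero;
  the tabulated SUVmax is then re-derived as the in-mask voxel maximum so
  the two modes agree in meaning. Two knobs (variance, correlation length)
  are enough to give all four texture families non-trivial values.

What the generator does **not** emulate: whole-body scan context, scanner
physics and reconstruction, attenuation, partial-volume effects, anatomical
plausibility of lesion placement, or PSA kinetics. Passing tests on
synthetic cohorts therefore demonstrate the *statistical machinery* —
silhouette correctness, calibration of the tests, monotone response to the
cohesion knob — not claims about any real patient population; real-cohort
summary values are expected to differ.

## Problem sizes and numerical conventions

Simulation-backed tests use cohorts of 20–100 patients and texture/VOI grids
of ≲ 25³ voxels — sizes at which every stochastic check (type-I error of the
screen at α = 0.001 over 2000 null replicates, 100-seed cluster recovery,
100-cohort silhouette bounds) is stable across seeds while the full suite
stays fast. Probability vectors must sum to 1 within 1e-9; z-scored columns
are validated to mean 0 / s.d. 1 within 1e-9; the silhouette implementation
is required to match its brute-force oracle within 1e-12. All randomness in
a run flows from a single seed (config hash and seed are echoed into the run
log).

## Known limitations

- The exact 42-feature roster of any given clinical software release may
  differ (e.g., SUVpeak or TLG in place of a texture feature); the roster is
  swappable but the default is this package's own fixed choice.
- First-order Energy and Uniformity coincide by construction under the
  histogram definition used here.
- Sphericity is mesh-based and carries voxelization error (documented
  above); values can marginally exceed 1 on near-spherical masks.
- The univariate screen treats lesion rows of one patient as independent
  observations when a patient-level split is applied at lesion level (the
  default); per-patient aggregation is provided for users who consider that
  pseudo-replication unacceptable.
- k selection by maximal mean silhouette is one defensible rule among
  several; it is asserted to recover planted structure, not claimed optimal.
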