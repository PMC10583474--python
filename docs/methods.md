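# Methods

## The problem

Before a major hepatectomy the liver is often "conditioned" so that the part
that will remain — the future liver remnant (FLR, also written FRL) — grows
large enough to sustain the patient. Two techniques dominate: ALPPS
(associating liver partition and portal vein ligation for staged hepatectomy),
which produces rapid hypertrophy over one to three weeks, and portal-vein
embolisation (PVE), which produces slower growth over one to three months.
Rapid regeneration inflates the *anatomic* remnant with oedema and venous
congestion that contributes volume but not function. CT volumetry alone
therefore overestimates the functional reserve, and a small functional remnant
is what drives post-hepatectomy liver failure (PHLF, ISGLS grades A/B/C;
grade ≥ B is the clinically severe endpoint).

This package implements and evaluates, on synthetic phantoms, a pipeline that
separates the *functional* remnant (FRFx) from the anatomic one using CT
texture: oedematous tissue is hypodense and differently textured from
functioning parenchyma, so a classifier over local texture statistics can
label remnant tissue as functional or oedematous and integrate the functional
volume. The volumetric indices are

- `FRLV% = FRL / (TLV − TV) × 100` and `FRFxV% = FRFx / (TLV − TV) × 100`,
  where TLV is the total liver volume and TV the tumour volume, both measured
  on the pre-conditioning study and held fixed as the normaliser;
- `iFRL%` and `iFRFx%`, the pre→post relative growth of each quantity;
- `sFLR% = FRL / (−794.41 + 1267.28 · BSA) × 100`, the remnant standardised to
  a body-surface-area estimate of total liver volume, with Mosteller
  `BSA = √(height·weight/3600)`;
- `KGR = ΔFRLV% / days`, the kinetic growth rate (a config switch
  `kgr_basis="sflr"` computes it on sFLR points instead).

## The phantom generator

No patient images are distributed with the study this emulates, so the
generator *is* the study population; its defaults are the study conditions,
not tuning knobs.

**Geometry.** A liver is an ellipsoid (aspect 1.00 : 0.96 : 0.92, centre
jittered ±1 mm) on a 64³ grid at 2.5 mm isotropic spacing (voxel
= 0.015625 cc). The FLR is the tissue on one side of a plane whose position is
chosen by cumulative voxel counting to hit the target volume fraction within
5%; conditioning moves the plane so the remnant grows from `pre` to
`pre · (1 + g)` while total anatomy is shared between the two studies. A
spherical tumour (median ≈ 35 cc, log-normal) sits in the non-remnant side
beyond the *post* plane so it never enters the remnant; random cylinders
(2–4.5 mm radius) cover ≈ 3% of the liver as vessels. Infeasible requests
(liver too large for the grid, no room for the tumour, remnant fraction
outside (0,1)) raise a `GeometryInfeasibleError` rather than clipping;
cohort sampling rejects and redraws such parameter sets.

**Truth composition.** The pre-study remnant is entirely functional. In the
post study a fraction θ of remnant parenchyma is oedema, placed as an outer
rim by converting the voxels nearest the remnant surface (by Euclidean
distance transform) until exactly `round(θ·n)` voxels are oedema — congestion
is peripheral in rapid regeneration, and a spatially coherent rim is a harder,
more realistic target for a patch classifier than scattered voxels. The rim
choice is ours; nothing in the emulated workflow prescribes a spatial pattern.

**Texture.** Each tissue class gets `μ + σ·G`, where G is white Gaussian noise
smoothed at a class-specific correlation length λ and renormalised over the
class's voxels, so each class's sample mean and standard deviation equal
(μ, σ) exactly. Defaults (HU, σ, λ in voxels): functional and non-remnant
liver (105, 12, 1.0); oedema (70, 20, 2.0); vessel (180, 10, 0.5); tumour
(45, 15, 1.5); background (−100, 15, 1.0). These are contrast-CT-plausible:
separable but overlapping. A zero-contrast variant gives oedema the
functional parameters and is used for null calibration.

**Cohort.** 24 cases, 11 ALPPS / 13 PVE. Per technique: θ ~ Beta with mean
0.45 (ALPPS) / 0.20 (PVE), concentration 10; growth g ~ Gamma (shape 9) with
mean 1.2 / 0.7; days to reassessment ~ Uniform{7..22} / {36..106}; pre-FLR
fraction ~ N(0.30, 0.05) / N(0.34, 0.05) truncated to [0.15, 0.5]; TLV ~
N(1420, 160) cc truncated to [1000, 1700] (the 160 mm grid box caps feasible
livers near 1.8 L); height ~ N(170, 10) cm and weight ~ N(75, 12) kg truncated
to their physiologic ranges. Growth is truncated so the post remnant stays
below 72% of the liver, which keeps tumour placement feasible; this mildly
clips the upper iFRL tail. Severe PHLF is drawn from
`P(≥B) = expit(2.0 − 0.08 · FRFxV%true)` — strictly decreasing in the true
functional percentage — with severe cases split C : B at 1 : 2 and non-severe
cases grade A with probability 0.22. Per-case randomness comes from child
streams spawned deterministically from the master seed, so every generator is
a pure function of (parameters, seed).

**What the phantom does not emulate.** Real vascular trees, respiratory
motion, CT reconstruction physics, partial-volume blur at organ boundaries,
inter-scanner variation, or livers whose post-conditioning volume exceeds the
pre-conditioning total (the plane moves inside a fixed ellipsoid, so
FRLV% ≲ 107%, whereas real series report values above 120%). Passing tests
therefore show the *pipeline logic* is sound under known truth — not that the
classifier transfers to patient images.

## Radiomic catalogue

106 features per whole-region vector: 19 first-order, 16 shape, 22 GLCM,
16 GLRLM, 16 GLSZM, 12 GLDM, 5 NGTDM, frozen with their order in
`radiomics/catalogue.json` (version 1.0). The total honours the emulated
workflow's printed feature count; the membership is this package's, chosen
from the standard families. Conventions:

- Discretisation: fixed bin width (default 25 HU) anchored at the region
  minimum, `bin(v) = floor((v − anchor)/width) + 1` — the
  reproducibility-standard choice for CT.
- First-order: population (1/n) variance; entropy in bits; Pearson kurtosis
  (Fisher + 3); skewness/kurtosis defined as 0 for regions without two
  distinct values; robust MAD over the closed 10–90 percentile sub-range
  (interpolated percentiles can exclude every sample in very small regions,
  in which case it is 0).
- Shape: surface and volume from marching cubes over a lightly smoothed
  (σ = 1 voxel) indicator — meshing the raw binary mask overestimates a
  sphere's surface by ~10% through staircase facets, while smoothing costs a
  few percent of volume on sharp-cornered solids; regions under 27 voxels use
  the raw binary surface, and single-voxel regions are flagged with a
  warning. Axis lengths come from 4√λ of the voxel-coordinate covariance
  eigenvalues. SphericalDisproportion is omitted as the exact reciprocal of
  Sphericity.
- Texture: 13 unique direction offsets at distance 1, symmetric co-occurrence,
  features computed per direction and averaged (GLCM, GLRLM); zones are
  26-connected (GLSZM); dependence counts 26-neighbours within grey tolerance
  α = 0 (GLDM); NGTDM neighbourhood means use in-mask 26-neighbours.
  Single-grey-level regions return closed-form constants (GLCM contrast 0 and
  correlation 1, NGTDM coarseness 10⁶, busyness/strength 0), never NaN.
- The analysis region is always FLR parenchyma with vessel and tumour voxels
  removed (a configurable dilation margin, default 0, widens the exclusion).

## Classification chain

The spatial unit is the non-overlapping 4³-voxel patch (1 cc at 2.5 mm):
64 voxels give texture statistics enough support while still localising a rim.
Patches with ≥ 50% parenchyma coverage are classified; parenchyma in
low-coverage patches inherits the nearest classified patch's label so that
every analysable voxel is assigned.

Training harvests labelled patches from a dedicated training cohort:
functional patches from pre-study remnants (pre-conditioning parenchyma is
taken as functional — the same labelling premise as the emulated workflow)
and from truth-functional post regions; oedema patches from truth-oedema
regions; post-study patches must be ≥ 90% pure in one truth class. Features
are standardised (z-score per column, constant columns dropped and recorded),
ranked by information gain — `IG = H(Y) − Σ_b p(b) H(Y|b)` in bits over
ten equal-frequency bins, which makes the ranking invariant to monotone
feature transforms; ties break lexicographically — and the top five feed an
L2-penalised logistic regression (strength 1.0 on standardised features,
lbfgs, threshold 0.5). A Student t screen (pooled variance) and an
exploratory k-means (k = 2, agreement with truth reported as max-matching
accuracy) are reported alongside but never gate the model: subgrouping is
evaluated, not used.

Patch-level selection draws only on the 15 *intensive* first-order features.
Energy and total energy are sums over in-mask voxels, and raw minima/maxima
are extreme order statistics, so on partially covered boundary patches they
track the voxel count — i.e. patch geometry, not tissue. Including them lets
a classifier "detect" a rim with zero texture contrast; excluding them keeps
the null calibration honest. Whole-region vectors always carry all 106
features. Higher-order texture families are likewise not extracted per patch
in the default configuration: the selection stage only ever consumes
first-order features, so per-patch texture matrices would cost an order of
magnitude of runtime without influencing any downstream number.

`FRFx` is the integrated in-mask volume of functional-labelled patches; the
estimated oedema fraction is `θ̂ = 1 − FRFx/FRL`. The estimate feeds the same
volumetry as the ground truth, so estimated and true indices are directly
comparable.

## Statistics

Mann-Whitney U uses mid-rank ties with an exact two-sided p by full
enumeration when `n1 + n2 ≤ 12` (the emulated severity split, 18 vs 6,
exceeds this and takes the approximation path), and a tie-corrected,
continuity-corrected normal approximation otherwise; two-sided
`p = 2·min(P(U′ ≤ U), P(U′ ≥ U))`, capped at 1. ROC curves sweep the unique
scores with half-credit ties, so the trapezoidal AUC equals
`U⁺/(n₊·n₋)` exactly; volumetric predictors of PHLF are scored
lower-is-positive (a small or slow-growing remnant predicts failure), so an
AUC above 0.5 means the clinically expected direction. Chi-square (Pearson,
no continuity correction), Spearman and Shapiro-Wilk delegate to scipy;
Shapiro-Wilk is a screening report only and never gates a test choice.
p-values are reported raw, with a no-multiple-testing-correction note, and
the severity table prints median (range) per group.

## Replicate studies and problem sizes

The package's own evaluation (in `frfx.studies`, driven by `analysis/` and
`scripts/acceptance.py`):

- **θ recovery** — 20 phantoms at θ ∈ {0, 0.25, 0.5, 0.75}; mean |θ̂ − θ|
  is ~0.02–0.04 at default contrast.
- **Direction reproduction** — the classifier is trained once, then applied
  to replicate 24-case cohorts (100 in the test suite, 60 by default in the
  acceptance script); per replicate the four predictors' AUCs for PHLF ≥ B
  are computed, and replicates with fewer than two cases on either side of
  the outcome are reported as NaN rather than silently resampled. Median
  AUCs land near 0.75 (FRFxV) versus 0.56–0.61 (FRLV), with sFLR and KGR
  near chance. The *ordering* is highly stable; the per-replicate win
  indicator is not: FRFxV beats FRLV in ~82% of replicates, and replacing
  the classifier with the ground-truth functional volumes does not raise
  this — at 24 cases with ~6 severe outcomes, paired-AUC sampling noise, not
  estimation error, is the ceiling.
- **Null calibration** — oedema given the functional texture and the outcome
  link flattened to P(≥B) = 0.25: balanced cross-validated patch accuracy
  (chance = 0.5 under the ~4:1 functional:oedema patch imbalance) and all
  predictor AUCs stay near 0.5 on a large cohort, guarding against the
  pipeline inventing oedema.
- **Growth dissociation** — anatomic growth iFRL separates ALPPS from PVE
  (p < 0.05 in ≳ 90% of replicates) while functional growth iFRFx does not
  (non-significant in well over 60%), the qualitative signature of
  oedema-inflated anatomic hypertrophy. This study runs on ground-truth
  volumetry without texture rendering, since the contrast is purely
  volumetric.

Problem sizes (64³ grids, 24-case cohorts, 60–100 replicates) are the
package's chosen desk scale: large enough that every stage runs at full
fidelity, small enough that the whole evaluation reruns in minutes.

## Design choices that were genuinely open

- The emulated workflow never quantifies "the defined threshold" of its
  logistic functional-volume classification; we classify tissue patches and
  integrate volume, which yields the same endpoint (an FRFx in cc) through a
  stated mechanism.
- Standardisation happens before feature selection (the order is unstated in
  the emulated workflow); IG on equal-frequency bins is unaffected either way.
- TLV − TV is measured pre-conditioning and reused as the post-study
  normaliser so pre/post percentages share a denominator.
- The k-means step is retained as an exploratory report, not a decision
  stage.
- NIfTI-1 (RAS+, spacing in the affine) is the interchange format; DICOM
  handling is out of scope.

## Known limitations

Phantom realism bounds every conclusion: tissue classes are stationary
Gaussian fields, organ boundaries are crisp, and the oedema rim is a single
connected shell. The catalogue's membership beyond the printed family counts
is this package's choice, as are the bin width and direction-averaging
conventions. The per-replicate instability of the AUC comparison at n = 24 is
a property of the cohort size, not of the method; conclusions at this scale
should rest on the replicate medians.
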