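# Methods

This note documents the models, operational definitions and numerical
choices behind `footssm`, in the order the pipeline applies them.

## Coordinate convention

All modules share one anatomical frame: +X anterior, +Y superior, +Z
toward the lateral side of a right foot; the floor is Y = 0. The sagittal
projection drops Z, the coronal projection drops X. Left feet are
standardized by negating Z and flipping triangle winding, which preserves
outward surface orientation and maps left varus/valgus onto the right-foot
sign convention.

## Synthetic cohort generator

**What it emulates.** A weight-bearing-CT-like cohort of three groups —
rectus, cavus, and chronic ankle instability (CAI) — whose radiographic
angles follow independent per-group normal distributions. Defaults are the
study conditions: group sizes 28/29/23; Meary's angle (MA) 0.2 ± 2.6,
17 ± 8.6, 12 ± 8.6°; hindfoot alignment angle (HAA) 9.8 ± 3.4, 5.9 ± 4.1,
6.0 ± 3.9°; calcaneal inclination (CI) 19 ± 3.6, 21 ± 3.1, 22 ± 3.1°;
46% left feet. The normal model is an assumption — only group summary
statistics are published, and the observed ranges hint at mild truncation,
which is deliberately not modeled.

**Geometry.** Each bone is a fixed-topology template: a subdivided
icosahedron scaled to anatomically plausible ellipsoid semi-axes
(162 vertices per bone), except the calcaneus, which is an extruded
pentagonal prism (234 vertices) whose inferior edge is a single straight
*keel* line of vertices extending posteriorly into the tuberosity region.
Anatomy is schematic; geometry is exact. The keel is the load-bearing
design element: any plantar landmark computed as a convex combination of
keel vertices lies exactly on the keel line at every pose, which is what
makes the angle planting closed-form.

**Kinematic construction (right foot), in order:**

1. **CI** — the calcaneus is pitched about the mediolateral (Z) axis.
   Because the subsequent coronal tilt shrinks the sagittal-projected
   slope by cos(HAA), the pitch is solved as
   θ = atan(tan(CI)/cos(HAA)), making the measured CI exact after both
   rotations.
2. **MA** — the talus is fixed at a −15° sagittal pitch; the five
   metatarsals rotate rigidly as a chain about a common pivot so the first
   metatarsal's long axis sits at exactly θ_talus + MA. MA = 0 gives
   collinear talar/first-metatarsal axes.
3. **HAA** — the calcaneus tilts about the anteroposterior (X) axis by
   −HAA under a vertical tibia. Both hindfoot-axis endpoints (tuberosity
   landmark and bone centroid) lie in the bone's z = 0 midplane by
   template symmetry, so the measured coronal angle equals the planted
   HAA exactly.

Global scale is a log-normal multiplier (σ = 0.05, always positive),
applied uniformly so angles are unaffected; GPA later removes it. Surface
noise is isotropic Gaussian per vertex, applied in the template's local
frame *before* posing, so world-frame group differences remain
attributable to the planted angles. The default noise SD is 0.3 mm,
sub-voxel for the 0.37 mm CT resolution the cohort emulates. Randomness is
keyed as (cohort seed, subject index, purpose), giving reordering-stable
per-subject substreams and fully independent cohorts for different seeds.

**What passing tests do and do not show.** The generator varies only three
pose parameters plus isotropic noise; real bones vary in intrinsic shape,
relative size, and correlated multi-bone geometry. Tests therefore
validate the *statistical machinery and the angle operators* — recovery of
planted effects, calibration under the null — not anatomical realism. In
particular, mode-1 variance fractions (~84%) are far higher than in real
cohorts (~37%), because the planted pose differences dominate a single
direction; the recovered quantity is the pattern of group separation, not
the variance fraction.

## Radiographic angle operators

No formulas are published for clinical 3-D measurement toolchains, so the
operators are explicit operational definitions validated against generator
ground truth (the module's central, documented substitution):

* **MA**: covariance principal axes (anterior-hinted) of talus and first
  metatarsal, projected to the sagittal plane; signed difference of their
  atan2 angles, positive in the cavus (apex-dorsal) sense.
* **CI**: the inferior calcaneal line runs from the plantar landmark of
  the posterior third to that of the anterior third (thirds by
  anteroposterior span); its sagittal angle against the floor is CI,
  positive when the anterior end is higher.
* **HAA**: tibial principal axis (superior-hinted) versus the calcaneal
  hindfoot axis — plantar tuberosity landmark to calcaneus centroid —
  both coronally projected; valgus (distal end lateral) is positive.

**Windowed-centroid landmarks.** Each plantar landmark is the centroid of
all vertices within 2.5 mm (in Y) of the region's plantar minimum, and the
tuberosity landmark reuses the posterior third's plantar landmark. A
single extreme vertex would carry the full surface-noise variance of one
point (unbounded Gaussian error); the windowed centroid averages several
keel vertices while remaining exactly on the keel line in the noiseless
case. Measured behavior: noiseless recovery < 1e-6° over the full planted
range (MA ∈ [−10°, 35°], HAA ∈ [0°, 19°], CI ∈ [9°, 27°]); at 0.5 mm
noise, mean absolute errors ≈ 0.16° (MA), 0.33° (HAA), 0.32° (CI), with
occasional ~1.5° tails when noise promotes a lateral-edge vertex into the
window. The noise-recovery contract is therefore stated and tested as a
mean absolute error bound (< 1°), not a per-draw worst case, which no
extreme-point landmark could satisfy with probability 1.

The foot-type rule is deterministic in MA alone: rectus iff
−4.5° ≤ MA ≤ 4.5° (inclusive; the cutoff absorbs rounding), cavus above,
"other" below.

## Correspondence and Procrustes frames

Correspondence is by construction: all subjects share template topology,
and particles are a fixed per-bone subsample of template vertex indices
(uniform stride over a label-seeded permutation, identical everywhere).
The default is 128 particles per bone (1,664 total over 13 bones); the
original study's per-bone particle counts are unpublished, and results
here are insensitive to the count (down-scaled runs use 32/bone). An
entropy-based particle optimizer is intentionally *not* reimplemented —
the analysis contribution is the statistics, not the optimizer. For
external meshes without shared topology, a nearest-vertex projection of a
reference subject's particles is provided as a clearly labeled
approximation.

**GPA (world frame).** Center; scale each configuration to unit centroid
size; rotate each to the current mean (rotation-only Kabsch, no
reflections); re-estimate and renormalize the mean; iterate until the mean
moves < 1e-8 (Frobenius) or 100 iterations. All steps are symmetric in the
subjects, so results are order-insensitive; the objective (sum of squared
distances to the mean) is non-increasing. Scaling is reserved for this
stage — ICP is rigid-only by design.

**Local frame.** Each bone independently is rigid-aligned (no scaling)
across subjects to its cohort mean. Whole-foot size is already removed,
and per-bone scale is genuine shape signal, so per-bone scaling is
deliberately omitted. The world/local contrast is what the particle maps
interpret: world-significant = alignment involved; local-significant =
intrinsic shape involved.

**ICP.** Point-to-point, single-direction nearest neighbor (source →
target vertices), rotation by SVD orthogonal Procrustes per iteration,
default tol 1e-6 mm / 100 iterations. The whole-foot stage aligns each
subject's pooled 13-bone cloud to a designated reference (first rectus
subject in manifest order — the choice of reference is a package decision,
not an established convention). Pooled-cloud alignment preserves
inter-bone pose, which the alignment-vs-shape analysis requires.

## Statistics

* **PCA**: column-mean-centered thin SVD; ≤ n−1 modes, numerically null
  directions trimmed; eigenvalues are score variances (ddof = 1); percent
  variances sum to 100.
* **Parallel analysis**: column-permutation nulls (each column of the
  centered matrix independently row-permuted), 1000 permutations, 95th
  percentile, strict inequality (a mode tying its threshold is *not*
  retained); retained count is the longest qualifying prefix. Permutation
  nulls were chosen over fresh Gaussian draws because they are
  distribution-free and standard in shape-model tooling. Eigenvalues are
  computed through the n×n Gram matrix when p ≫ n.
* **KS normality**: one-sample KS against a normal with estimated
  mean/SD, asymptotic p (the conventional reading of "KS normality
  test"); the stricter Lilliefors correction is available behind a flag.
* **ANOVA battery per retained mode**: classical one-way ANOVA with
  explicit sums of squares; Tukey–Kramer studentized-range pairwise p
  (exact SE for unequal n); η² = SS_between/SS_total with the 0.01 /
  0.06 / 0.14 small/medium/large benchmarks. Modes are tested without
  cross-mode multiplicity correction — a deliberate match to common
  practice in this analysis style, and a statistical caveat: with k
  retained modes the familywise rate across modes is ~1 − 0.95^k.
* **Radiographic measures**: Welch's ANOVA (weights nᵢ/sᵢ²,
  Welch–Satterthwaite df) with Games–Howell post hoc (per-pair Welch t,
  q = t√2) and Hedges' g (pooled SD with J = 1 − 3/(4N − 9); 0.20 / 0.50 /
  0.80 benchmarks) — robust to the unequal group variances the MA
  distributions show.
* **Per-particle Hotelling T²**: two-sample T² on 3-D particle
  coordinates, F-referenced with p = 3; Benjamini–Hochberg FDR applied
  separately within each frame across particles (BH chosen as the default
  FDR flavor; applied per frame per group pair, not pooled). Particles
  with singular pooled covariance are logged and classified "none" rather
  than aborting the map. Classes: alignment_only (world significant
  only), shape_only (local only), alignment_and_shape (both), none.

Every statistic is validated in the suite against an independent oracle:
closed-form identities (two-group Tukey = pooled t, two-group Welch =
Welch t, 1-D Hotelling = t², Hedges J closed forms), a 10,000-draw
permutation test for the Hotelling p, hand-computed BH step-up, reference
implementations (scipy, statsmodels, pingouin, scikit-learn PCA), and
type-I calibration simulations (Tukey familywise rate within the binomial
CI of α; Welch null retention ≥ 93%; particle maps ≤ 7% flagged under the
null).

## Pipeline, determinism and problem sizes

Stages: simulate → measure → ssm → stats, orchestrated by a validated
configuration (YAML/JSON, exhaustive schema errors, unknown keys
rejected). With an output directory set, each stage writes artifacts plus
a marker keyed by the SHA-256 configuration hash; re-running an unchanged
configuration reloads completed stages. The report JSON is reproduced
byte-identically (timings aside) for identical config + seed.

Default problem sizes were chosen so the full pipeline (80 subjects,
128 particles/bone, 1000 permutations) completes in well under a minute on
one CPU, and the multi-seed suites (20-seed recovery sweep, 20-seed null
calibration, 1000-rep type-I simulations) keep the whole test suite to
roughly a minute. Down-scaled runs (8–32 particles/bone, 100–500
permutations, smaller groups) are used where a property does not depend on
the full resolution.

## Known limitations

* Bone shape variation beyond the three planted pose parameters is absent;
  shape-only effects are exercised only via noise and constructed cases.
* The normal angle model ignores the truncation suggested by published
  ranges, and angle draws are independent within subject (real MA/HAA/CI
  co-vary).
* The hindfoot-axis and inferior-calcaneal-line constructions are one
  defensible operationalization among several used clinically; absolute
  angle values from other toolchains may differ by a constant convention
  offset even when group contrasts agree.
* The ICP reference subject and the single-template correspondence are
  conveniences of the synthetic setting; applying the pipeline to real
  segmentations requires an external correspondence model and should use
  the provided projection only for exploration.
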