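# footssm

Multi-bone statistical shape modeling (SSM) of foot and ankle morphology,
for biomechanics and orthopaedics researchers studying how bony alignment —
in particular cavus-like features — relates to conditions such as chronic
ankle instability (CAI). The package provides a complete, tested analysis
pipeline over per-subject sets of 13 bone surface meshes (calcaneus,
cuboid, the three cuneiforms, metatarsals 1–5, navicular, talus, tibia):

* a **synthetic cohort generator** that builds schematic, fixed-topology
  feet whose radiographic angles are planted by construction, emulating a
  weight-bearing-CT cohort of 28 rectus, 29 cavus and 23 CAI feet with
  group-wise Meary's angle (MA), hindfoot alignment angle (HAA) and
  calcaneal inclination (CI) distributions;
* **mesh utilities**: PLY/STL/OBJ I/O, left-to-right mirroring, principal
  axes, and rigid iterative-closest-point alignment;
* **correspondence and Procrustes**: per-bone particle systems with
  cross-subject correspondence, whole-foot generalized Procrustes analysis
  (GPA, with scaling) for the *world* frame and rigid per-bone alignment
  for the *local* (pure shape) frame;
* **shape statistics**: PCA modes of variation, permutation-based parallel
  analysis for mode retention, per-mode KS normality / one-way ANOVA /
  Tukey–Kramer post hoc / η² effect sizes, Welch's ANOVA with Games–Howell
  and Hedges' *g* for radiographic measures, and per-particle two-sample
  Hotelling's T² maps with Benjamini–Hochberg FDR control that classify
  each correspondence particle as an *alignment* and/or *shape* difference;
* **computational radiographic measurements**: MA, HAA and CI derived
  directly from the 3-D meshes, plus the MA-based rectus/cavus foot-type
  rule (rectus iff −4.5° ≤ MA ≤ 4.5°).

## The model in brief

Each subject is represented by ordered correspondence particles
x<sub>i</sub> ∈ ℝ<sup>3P</sup> over all bones. After GPA (centering,
scaling to unit centroid size, rotation to the cohort mean), PCA gives
modes **v**<sub>k</sub> with eigenvalues λ<sub>k</sub>; a mode is retained
when its eigenvalue exceeds the 95th percentile of column-permutation null
eigenvalues at the same rank (parallel analysis). Group differences are
tested per retained mode on the PCA scores, and per particle with
T² = (n<sub>a</sub>n<sub>b</sub>/(n<sub>a</sub>+n<sub>b</sub>)) d′S⁻¹d in
both frames: a particle significant in the world frame (pose preserved)
involves an alignment difference; significant in the local frame (per-bone
rigid alignment removed) involves an intrinsic shape difference.

Angle operators are explicit operational definitions: MA is the signed
sagittal angle between the talar and first-metatarsal principal axes
(positive = apex-dorsal/cavus), CI is the sagittal pitch of the inferior
calcaneal border line against the floor, HAA is the signed coronal angle
between the tibial axis and the calcaneal hindfoot axis (valgus positive).
On noiseless generated feet these operators recover the planted angles to
better than 1e-6 degrees — the generator/measurement fixed point that
anchors the whole test suite.

## Worked example

```python
from footssm import build_parametric_foot, measure_angles, classify_foot_type

foot = build_parametric_foot(ma=17.0, haa=5.9, ci=21.0, noise_sd=0.3, seed=4)
m = measure_angles(foot)
print(f"MA {m.ma:5.1f} deg   HAA {m.haa:4.1f} deg   CI {m.ci:4.1f} deg   "
      f"foot type: {classify_foot_type(m.ma)}")
```

prints

```
MA  17.2 deg   HAA  6.3 deg   CI 20.8 deg   foot type: cavus
```

— a foot built at the cavus group means, measured back with 0.3 mm surface
noise: the angles return within a few tenths of a degree and the MA rule
classifies it as cavus. Running the full pipeline on the standard cohort:

```python
from footssm import GeneratorParams, RunConfig, run_pipeline

cfg = RunConfig(generator=GeneratorParams(), particles_per_bone=64,
                n_permutations=500, seed=1)
rep = run_pipeline(cfg)
```

reports (seed 1): 3 retained modes; mode 1 carries 84.3% of the variance
with a large effect size (η² = 0.44) separating rectus from both cavus and
CAI; the particle maps flag ~99.5% of particles (almost entirely
*alignment-only*) for CAI-vs-rectus and cavus-vs-rectus but only 0.1% for
CAI-vs-cavus — the CAI group's morphology is cavus-like, and the difference
between them is the smallest of the three comparisons. On this schematic
generator the planted pose differences dominate a single mode, so mode-1
variance is far higher than in real anatomies; the *pattern* of group
separation is the recovered quantity.

The same pipeline is scriptable from the shell:

```bash
footssm all --seed 1 --out results/
```

which writes `results/report.json` (schema: group sizes, per-mode
statistics, radiographic Welch/Games–Howell tables, particle-map class
percentages, provenance with config hash) plus per-stage artifacts, and
caches completed stages keyed by the configuration hash.

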