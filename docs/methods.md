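# Methods

This note documents the models behind `rewardnet`, the defaults and why
they were chosen, what the simulations do and do not emulate, and the
numerical decisions a user auditing results should know about. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## 1. Digital fiber phantoms

A phantom is a voxel grid (default 32³ at a nominal 1.7 mm isotropic
spacing, matching a high-resolution DWI protocol) containing a fiber
bundle defined by a centerline polyline and a tube radius of half the
cross-section. Three geometries are provided: a straight bundle, a
quarter-arc curved bundle (arc radius chosen to fit the grid, so the
per-voxel turn is a few degrees — far below the 45° stopping rule), and
two parallel bundles (a specificity control: their connectivity must stay
block-diagonal). Bundle voxels carry a prolate tensor with eigenvalues
(1.7, 0.3, 0.3)×10⁻³ mm²/s — white-matter-like diffusivities whose
closed-form FA is ≈ 0.799 — oriented along the local tangent; the
background is isotropic at the trace-matched mean diffusivity
0.76×10⁻³ mm²/s, so its FA is exactly 0.

Each bundle ends in a 1-voxel-thick labeled cap placed on the straight
continuation of the centerline. Caps are not white matter (they are not
seeded) but carry the bundle tensor and belong to the tracking mask, so
streamlines can enter them before leaving the mask — this realizes the
"touching both regions" edge definition. The ground-truth
`expected_nos` equals the number of bundle voxels: for straight
geometries every seed lies on a principal-direction line between the two
caps, so the count is exact; for the curved bundle it is an upper bound
(seeds near the tube wall can drift out sideways, which the tests account
for by requiring end-to-end connection rather than the full count).

Signals follow the single-tensor model S(g) = S₀·exp(−b gᵀDg) with
b = 1000 s/mm², 60 gradient directions and one b = 0 volume by default.
Directions come from a spherical Fibonacci lattice — deterministic,
approximately uniform, and serialized with the phantom as FSL-style
`bvals`/`bvecs` text. Noise, when requested, is Rician (the magnitude of
a complex Gaussian), the correct model for magnitude MR data;
`noise_sigma = 0` bypasses the noise path entirely so that exactness
tests are meaningful.

What the phantoms do **not** emulate: crossing/kissing fibers, partial
volume at bundle edges, susceptibility or eddy-current distortion, and
the parietal fat-suppression rim artifact (handled in real data by a
manual rating consumed as metadata). Passing phantom tests therefore
demonstrates correctness of the reconstruction chain on well-posed
single-fiber geometry, not robustness to those real-data effects.

## 2. Tensor fitting

S₀ is the mean of the b < 50 s/mm² volumes. The six unique tensor
elements solve the log-linearized system ln(S/S₀) = −b gᵀDg over the
b > 0 volumes, by ordinary least squares or, for `method="robust"`,
iteratively reweighted least squares with a Tukey biweight
(tuning constant 4.685, at most 20 iterations, convergence tolerance
10⁻⁶ on the coefficient change) on residuals standardized by the MAD
(falling back to the mean absolute deviation when the MAD degenerates to
zero, as it does for clean signal plus a few outliers). The Tukey choice
is a conventional redescending estimator, made concrete here because
"robust tensor fitting" admits several implementations; it is a
configurable stand-in, not a claim about any particular legacy script.
Nonpositive signals are floored at 10⁻¹⁰ before the log and receive zero
prior weight in robust mode. Negative eigenvalues are clamped to zero
before FA; voxels with all-zero signal are flagged and excluded from
tracking. Where λ₁ = λ₂ the principal eigenvector is whichever unit
vector the symmetric eigendecomposition returns — a measure-zero tie on
continuous data, deterministic per run.

## 3. FACT tracking

One seed per white-matter voxel center, propagated in both ±v₁
directions. The step is the defining FACT geometry: an exact ray-box
intersection with the current voxel's axis-aligned faces, recording a
point at every boundary crossing; the next voxel's direction is adopted
with its sign aligned to the incoming direction. Corner/edge ties in the
intersection are resolved by advancing half a voxel along the ray and
taking the containing voxel — deterministic and orientation-independent.
A direction terminates when the next voxel is outside the tracking mask
(`left_mask`), has undefined tensor or FA below 0.1 (`low_fa`), or would
require a turn of **strictly more than** 45° (`sharp_turn`); a safety cap
of 10 × the largest grid dimension steps (`max_steps`) guarantees
termination on pathological direction fields and cannot trigger on
well-posed ones. Half-tracks are concatenated; tracks visiting fewer
than `min_length = 3` distinct voxels are discarded (a configurable
suppression of single-voxel artifacts; the underlying method description
is silent on this, so the knob is exposed openly). Tracking is
deterministic and invariant to global sign flips of v₁.

## 4. Connectome

A streamline touches a region if any voxel it visits carries that label
(pass-through semantics). This is the literal reading of "touching both
regions"; since endpoint-only counting is also defensible, it is
available via `touch="endpoints"`. A streamline touching ≥ 3 regions
increments every pair it touches — the direct consequence of the
pairwise definition. The FA edge weight is the mean of the FA map over
the **union of distinct voxels** visited by that pair's streamlines
(voxels shared between streamlines count once: the definition names
voxels, not per-streamline means). Matrices are symmetric with zero
diagonal, and an FA edge exists exactly where a NOS edge does.

The standard node table maps 68 cortical Desikan-Killiany labels plus 14
subcortical structures to 82 nodes, with the ten reward nodes flagged
(bilateral lateral/medial orbitofrontal cortex, caudate, putamen,
accumbens); phantoms use ad-hoc small tables.

## 5. Graph metrics

CS is the mean over all N(N−1)/2 unordered pairs **including absent
(zero) edges** — "average connectivity between all pairwise regions"
reads as all pairs. The weighted clustering coefficient is the
geometric-mean (Onnela-type) triangle intensity with k_i the **binary**
degree and nodes of degree < 2 assigned C_i = 0, matching the de-facto
standard toolbox implementation; the tests cross-check it against an
independent brute-force triangle enumeration and against networkx. NOS
weights are scaled to [0, 1] by the maximum of the network at hand
(reward and whole-brain networks each by their own maximum) before the
CC, which makes the NOS CC invariant to uniform weight rescaling; FA
weights already live in [0, 1] and are not rescaled. Reward metrics and
node-wise metrics are divided by the corresponding whole-brain *network*
metric (a per-node whole-brain divisor is the natural alternative; the
network-level divisor is the default). A zero whole-brain denominator
yields NaN and an explicit flag, never a silent 0.

## 6. Quality control

Framewise displacement: FD_t = Σ|Δtranslation| + 50 mm·Σ|Δrotation|,
rotations as arc length on a 50 mm sphere per the standard head-motion
summary; the first frame has FD 0 and is excluded from the mean.
Motion tables are read as 6-column text, rotations-first by default (the
eddy-correction convention), configurable. Connectome screening computes
per subject the mean NOS and mean FA over existing (nonzero-NOS)
connections and the prevalence of existing/non-existing connections,
then flags values outside Q1 − 2·IQR / Q3 + 2·IQR. Quartiles use linear
interpolation at positions p·(n−1) — the convention must be pinned for
reproducible flags, and this is the common default. Screening is
single-pass (fences are not recomputed after exclusions), matching a
one-shot QC round; severe artifact ratings exclude a scan outright.
Skewed covariates are log-transformed: ln(mean FD) and ln(CES-D + 1) —
the +1 offset is forced by legitimate CES-D scores of 0.

## 7. Cohort simulation

The generator is the generative counterpart of the models fitted
downstream, with defaults fixed once from the demographic profile of a
middle-aged population cohort (n = 347; age ~ Uniform(20, 59); sex
balanced; BMI mean ≈ 25.7, SD ≈ 3.6 kg/m²; mean FD ≈ 0.62 ± 0.13 with a
mild BMI dependence, reflecting the BMI-motion collinearity that
motivates motion adjustment; CES-D gamma-distributed with mean ≈ 9.5;
smoking 175/79/83 and education 9/190/146 category weights; missingness
10/347, 2/347 and 21/347 for smoking, education and CES-D, so listwise
ns vary across models as they do in practice). Genotypes are drawn at
Hardy-Weinberg proportions with risk-allele frequencies 0.42 (FTO,
additive 0/1/2 coding) and 0.15 (Taq1A, carrier coding). BMI receives an
additive FTO effect of 1.0 kg/m² per risk allele — back-computed so the
AT-vs-TT contrast lands near t ≈ 2.7 at the stated group sizes. Each
network metric is intercept + β·BMI + covariate effects + Gaussian
noise; the planted β values (−0.00089, −0.02, −0.0025, +0.31 for FA CS,
FA CC, NOS CS, NOS CC) and node-wise slopes are taken from the reported
regression scale, with residual SDs back-computed from the printed 95%
CI widths via SE ≈ σ/(σ_BMI√n). A linear-Gaussian generator reproduces
the estimand structure, not the physiological coupling of the metrics
(e.g. network metrics are generated independently given BMI, whereas
real CS and CC share a connectome).

## 8. Inference

All models are ordinary least squares with treatment coding against the
lowest category level. Nested comparisons use
F = ((RSS₀ − RSS₁)/Δdf)/(RSS₁/(n − p₁)) on the listwise-complete subset
of the full model (the null's variables are a subset, so rows coincide);
the genotype-interaction comparison is additionally reported as a
Gaussian likelihood-ratio χ², since that comparison is named as a
chi-square test. Focal coefficients carry normal-theory (t-based)
two-sided p-values and 95% CIs; no robust/sandwich errors. Bonferroni
families are {4 network metrics} → α = 0.0125 and {10 nodes} →
α = 0.005, with no correction across edge types. The confounder-adjusted
model is gated on Bonferroni network-level significance, node-wise
models on nominal (α = 0.05) significance of the edge type — mirroring a
staged analysis in which FA reached nominal but not corrected
significance yet was followed up node-wise. Sensitivity refits drop BMI
values above Q3 + 1.5·IQR (upper fence only); exploratory comparisons
add sex×BMI and age×BMI interactions to the strength metrics.
Collinear designs raise an error naming the aliased columns.

Genetics utilities: MAF folds the alternate-allele frequency to
[0, 0.5]; the Hardy-Weinberg test is a Pearson χ² (df = 1, no continuity
correction) against expectations from the observed allele frequency —
it errors on monomorphic input rather than dividing by zero. Power for
the two-sided two-sample t-test uses the noncentral t distribution with
δ = d/√(1/n₁ + 1/n₂).

## 9. Calibration and problem sizes

`scripts/acceptance.py` and the acceptance tests run the statistical
calibration at the study's own scale, n = 347 per replicate: 1000 null
replicates for the type-I error of the Model-1 comparison (band
0.05 ± 0.02), 2000 replicates for 95% CI coverage (band 0.95 ± 0.02),
and 500 replicates for recovery of the planted NOS CS coefficient
−0.0025 (bias bounded by 3 Monte-Carlo standard errors). Phantom checks
use a 9×9×26 grid with a 3×3×20-voxel bundle (180 seeds) and a 32³
curved-bundle grid — sizes chosen so the whole suite runs on a desktop
in about a minute while the geometric oracles remain exact.

## 10. Known limitations

- Single-tensor model only: no multi-shell, kurtosis or CSD modeling,
  and no crossing-fiber phantoms; FACT on crossing geometry would follow
  the majority eigenvector, which no test here exercises.
- No eddy/susceptibility correction is performed; motion parameters are
  consumed, not estimated.
- The simulated cohort is linear-Gaussian by construction; calibration
  results certify the inference machinery under its own assumptions, not
  robustness to non-Gaussian metric distributions.
- Parcellations are consumed as label volumes; cortical reconstruction
  is out of scope.
- The printed Hardy-Weinberg statistics of the motivating cohort were
  evidently computed on a larger genotyping sample than the analysis
  subset; the HWE operation is therefore validated on constructed
  counts with hand-computed expectations instead.
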