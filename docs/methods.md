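# Methods

`pvstwin` implements a two-part computation: (1) fully automated segmentation
of MRI-visible dilated perivascular spaces (dPVS) on 3D T2-like volumes, and
(2) classical-twin ACE heritability analysis of the resulting regional
volumes. Because the cohort this emulates (healthy young adult twins and
siblings with 0.7 mm isotropic 3D T2 imaging) is access-restricted, every
input is produced by the package's own generators, and all validation runs on
that synthetic world. This note records the models, the defaults and why, and
what a green test does and does not establish.

## 1. Synthetic world

### Phantoms

A phantom is a schematic head on a 96³ grid of 0.7 mm isotropic voxels: an
ellipsoidal brain whose outer ~2.5-voxel rind is a bright CSF-like
subarachnoid shell, two deep-grey (basal ganglia, BG) blobs with adjacent
bright ventricles, and white matter (WM) filling the rest. dPVS are rendered
as bright capsules (segment plus radius) carved entirely inside WM or BG,
radii 0.35–1.4 mm so every diameter stays below the 3 mm that defines a dPVS.
Ground truth is exact: the per-region true volume is the carved voxel count
times 0.343 mm³.

Intensities follow T2 contrast (tissue 100, CSF and tubes 200, background 0).
Corruption is a smooth multiplicative bias field (amplitude 0.05) followed by
additive Gaussian noise (SD 5, i.e. SNR 20 for tissue) — Rician noise is
deliberately not modelled; at the high SNR of 3D T2 SPACE acquisitions the
Gaussian approximation is standard. Test–retest replicates reuse the
noise-free render with a fresh noise/bias realization, emulating a second
acquisition of unchanged anatomy.

Tube placement is uniform within the region mask (the literature gives no
usable spatial statistics for dPVS clustering); anatomy is schematic, not
atlas-based, because the segmentation pipeline only ever consumes region
masks, which are external inputs for real data too.

The one deliberate imperfection: `segmentation_masks` dilates the anatomical
WM/BG masks by 2 voxels before segmentation, so they leak into the ventricle
and subarachnoid borders. This reproduces the situation with real
FreeSurfer-derived masks, where mask leakage is exactly what creates the
false positives the CNN refinement stage exists to remove. With perfect
masks the phantom produces no false-positive components at all and stage 2
has nothing to do.

### Twin cohorts

Cohorts follow the classical twin design: 138 monozygotic (MZ), 79 dizygotic
(DZ) and 133 nontwin-sibling (NT) pairs by default (700 subjects, 350
families). Within a pair, the additive-genetic latent A correlates by the
relatedness r_A (1 for MZ; 0.5 for DZ and NT, constructed exactly as
A₂ = 0.5·A₁ + √0.75·Z), the shared-environment latent C is identical, and the
unique-environment latent E is independent. Traits are
covariates + a·A + c·C + e·E with scalar paths, or the lower-triangular 2×2
Cholesky analogue for two traits. Twins share age and sex within pair; NT
siblings draw both independently (ages uniform over 22–35 years, sexes
independent, so about half of NT pairs are opposite-sex) — mirroring the
cohort structure where sibling pairs, unlike twin pairs, have nonzero age and
sex differences. Default covariate slopes are 0.3 per SD of age and 0.2 for
male sex, modest effects of the size the cohort analyses report
qualitatively; they exist so the residual-adjustment stage has real work to
do and are independent of A/C/E by construction.

## 2. Segmentation stage 1: vesselness

The image is z-scored over the brain mask (population SD; the convention is
fixed for determinism, and the choice is immaterial downstream because the
vesselness ratios are scale-free in the eigenvalue ratios and γ adapts to the
volume). Hessians are computed from DC-corrected Gaussian derivative kernels
(the sampled second-derivative kernel's small nonzero response to constants
is removed, so constant volumes map exactly to zero) in physical units,
scale-normalized by scale². Eigenvalues |λ1| ≤ |λ2| ≤ |λ3| feed the standard
bright-tube vesselness

V = (1 − exp(−R_A²/2α²)) · exp(−R_B²/2β²) · (1 − exp(−S²/2γ²)),

zero wherever λ2 > 0 or λ3 > 0, with R_A = |λ2|/|λ3|, R_B = |λ1|/√|λ2λ3|,
S = ‖λ‖₂. Defaults: α = β = 0.5; γ adaptive at half the maximum S over the
masked volume per scale; scales {0.7, 1.05, 1.4} mm spanning the sub-3 mm
dPVS calibre at 0.7 mm voxels; multiscale combination by per-voxel maximum;
thresholding after the multiscale maximum.

The threshold default is 0.25 in some descriptions of this family of
pipelines, but on noise-free phantoms that retains only ~55% of true tube
volume (tube-surface voxels respond weakly). The shipped default is 0.10,
at which candidate volume lands within ±10% of truth across seeds with a
pre-refinement false-positive fraction of ~0.13. The threshold remains a
config knob.

Candidates are 26-connected components (tubes at oblique angles fragment
under 6-connectivity) inside the supplied WM ∪ BG masks, each tagged by the
region holding the majority of its voxels, ties toward WM.

## 3. Segmentation stage 2: CNN refinement

A 3-class 3D patch classifier (class 1 dPVS, class 2 ventricle-adjacent
false positive, class 3 subarachnoid false positive) decides per component
whether to keep it; classes 2 and 3 are removed whole, so refinement can only
shrink the candidate set. The architecture is fixed: 3×3×3 convolutions with
"same" padding, channels 8/16/32/32, ReLU after each convolution, 2×2×2
max-pool after each pair of convolutions (24 → 12 → 6), one fully connected
layer of 128 units, 3-way softmax, cross-entropy loss. "Same" padding is the
one padding choice under which the stated pool placement reproduces the
stated patch side exactly.

The network is implemented directly in NumPy (im2col convolutions in
float32, manual backprop) because no GPU framework is assumed in the target
environment; at one 24³ patch per candidate component the cost is trivial.
Training uses plain SGD with momentum 0.9, learning rate 0.001 (0.01
oscillates and can diverge on these data), batch size 8, and balanced class
sampling: each mini-batch slot first draws a class uniformly, then a patch
uniformly within the class, so classes enter at uniform frequency regardless
of raw counts. Augmentation per patch: independent axis flips (p = 0.5),
additive Gaussian noise (SD 0.1 in z-score units), additive bias (SD 0.1),
multiplicative scaling (1 + N(0, 0.1²)); amplitudes are configurable since no
canonical values exist.

Classification is per connected component with the patch at its centroid.
Training labels come from phantom ground truth: a component overlapping true
tube voxels is class 1; otherwise within 2 voxels of a ventricle, class 2;
otherwise within 2 voxels of the subarachnoid shell, class 3; anything left
is assigned to the nearer of the two confounders. This replaces manual
labelling, which is the one supervised ingredient real-data use would need
to supply.

## 4. Volumetry, reliability, validity

Regional volume is voxel count × voxel volume (0.7³ = 0.343 mm³ at default
spacing). Agreement between paired measurements uses the one-way
random-effects single-measure ICC, (MSB − MSW)/(MSB + MSW) for two
measurements per unit — chosen because it is exchangeable in member order,
which is the right property both for test–retest and for twin within-pair
use; ICC(2,1) (two-way absolute agreement) is available behind a flag.
Validity against ground truth reports the false-positive volume fraction
normalized by automated volume and the false-negative fraction normalized by
truth volume — the only pairing of denominators under which an
under-segmenting method can coherently show 0% FP alongside a nonzero FN
fraction. Fractions are computed whole-volume on phantoms (real-data
protocols often score index slices; with exact digital ground truth there is
no reason to subsample).

## 5. Covariate adjustment

Phenotype and continuous covariates are z-scored (sample SD); binary
covariates (sex, dichotomized ethnicity) are 0/1-coded. The phenotype is
replaced by the re-standardized residuals of a pooled OLS fit on the chosen
covariate set; family clustering is deliberately ignored at this step (it
enters through the twin models) and residuals are re-standardized because
heritability is scale-invariant either way, so the choice is cosmetic but
fixed. Named covariate sets mirror the study ladder: unadjusted (age, sex),
partially adjusted (+regional volume or +ICV), completely adjusted (+both).

## 6. Twin ACE models

For one trait, a pair is bivariate normal with variance a² + c² + e² and
within-pair covariance r_A·a² + c²; h² = a²/(a² + c² + e²). For two traits,
lower-triangular path matrices L_A, L_C, L_E give component covariances
A = L_A L_Aᵀ etc. (PSD by construction); the 4×4 pair covariance has
within-person block A + C + E and cross-person block r_A·A + C. From the
genetic paths, r_g = a12/√(a12² + a22²) — identical to the A-matrix
correlation whenever a11 > 0, which the code cross-checks — and shared
heritability |a11·a12|/(|a11·a12| + |c11·c12| + |e11·e12|), with absolute
values so the quantity stays a proportion when cross paths go negative (the
signed ratio is available and reported when it differs).

Fitting maximizes the exact normal log-likelihood summed over pairs, with
group-specific r_A (DZ and NT enter as separate groups sharing r_A = 0.5, so
per-group diagnostics remain available), one free mean per trait shared
across groups (traits are standardized residuals; group means are a flag),
univariate paths bounded nonnegative, and bivariate cross paths free in sign.
Likelihoods are evaluated from per-group sufficient statistics (n, sum,
scatter), making an evaluation O(1) in cohort size; optimization is L-BFGS-B
from a Falconer moment start (a² = 2(r_MZ − r_0.5), c² = 2r_0.5 − r_MZ,
clipped) plus five fixed-seed random restarts, best likelihood wins. Model
comparison: AE/CE/E fix dropped paths at zero; LRT 2Δloglik against the
naive χ²(df = dropped paths) reference (conservative at the a = 0 boundary;
the ½χ²₀+½χ²₁ mixture is noted but not default, matching common SEM
practice); AIC = −2·loglik + 2·(free parameters).

Confidence intervals are profile-likelihood: the set where the profile
deviance stays below the χ²(1) quantile, bisected on each side and clipped to
the quantity's natural range; estimates on a range boundary yield one-sided
intervals. For univariate h² the profile is computed by exact
reparameterization (total variance, c-share, mean at fixed h²); for r_g and
shared h² by SLSQP equality-constrained refits. A family-resampling
percentile bootstrap is the alternative.

### Known finite-sample behaviour

The constrained-ML h² estimator is consistent but not unbiased. When the
generating c² is essentially on the c² ≥ 0 boundary (e.g. a² = 0.902,
c² = 0.02), the boundary truncates the sampling distribution and costs about
3 percentage points of downward bias in the mean ĥ² at 138/79/133 pairs
(measured: mean ĥ² ≈ 0.869, consistent at large n: 0.903 at 2000/1000/1000
pairs). Any path-parameterized SEM fit shares this behaviour; it is a
property of the estimator, not of this implementation — the likelihood
matches a brute-force per-pair density sum to machine precision and the
optimizer matches dense random search. Away from the boundary (a² = 0.658,
c² = 0.16) the mean recovery is exact to < 1 point.

## 7. What green tests establish — and what they don't

The synthetic world exercises every code path with exact ground truth, so
green tests establish internal correctness: formulas match oracles,
estimators are consistent, the pipeline is deterministic under seeds, and
each stage's contract holds. They do not establish performance on real MRI:
phantom anatomy is schematic, noise is Gaussian and stationary, tube
intensity is uniform with no partial-volume texture, and the CNN's three
classes are cleanly separable by construction. Real-data use would need
manual patch labels, FLAIR-based discrimination of white-matter
hyperintensities (explicitly out of scope), and revalidation of the
vesselness threshold.

## 8. Reproducibility

Every stochastic routine takes a seed; the pipeline fans a single global seed
out to per-stage seeds by a fixed splitting rule and records every output
file's SHA-256 in a manifest. Optimizer restarts use fixed internal seeds, so
fits are deterministic given the data.
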