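# Methods

This note documents the models, numerical choices and known limitations
of `sbmorph`. It is the package's own account of what it computes;
every empirical figure quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## The decomposition model

The data matrix X (n subjects × V in-mask voxels) is assumed to be a
noisy linear mixture of k spatial sources: X = A·S + E. Spatial ICA
orientation is used throughout — sources are voxel patterns, mixing
columns are per-subject loadings. The pipeline:

1. **Per-voxel centering.** The mean across subjects is removed from
   every voxel column. (Whether one should center voxels, subjects, or
   both is a genuinely open choice for SBM; per-voxel centering is
   required for covariance-based order estimation and is what the MDL
   and whitening stages here assume.)
2. **MDL order selection.** With the V voxels treated as observations
   of the n-dimensional subject vector, the eigenvalues λ₁ ≥ … ≥ λ_p of
   (1/V)·XcXcᵀ (near-zero eigenvalues dropped at a relative tolerance of
   1e-10, which removes the one annihilated by centering) score each
   candidate order k as

       MDL(k) = −V (p−k) log(GM_k/AM_k) + ½ k (2p−k+1) log V,

   GM/AM the geometric/arithmetic means of the p−k smallest eigenvalues;
   the arg-min over k ∈ [1, p−1] is returned, so pure noise yields the
   minimum allowed order 1. This is the classic i.i.d.-sample form; no
   correction for spatially correlated samples is applied, so the order
   estimate inflates on heavily smoothed data. The pipeline therefore
   accepts a user override (`--k`), and order-recovery validation is run
   on unsmoothed synthetic matrices, where the i.i.d. assumption holds
   (the synthetic sources are already spatially smooth).
3. **Whitening.** Rank-k SVD whitening in subject space; Y = √V·Vᵀ_k has
   identity covariance across voxels and dewhitener·Y is exactly the
   rank-k PCA reconstruction. Eigenvector signs are canonicalized
   (largest-magnitude subject weight positive) so the whitening is
   deterministic.
4. **Infomax ICA.** Full-batch natural-gradient ascent with the logistic
   score, W ← W + η(I + (1−2g(u))uᵀ/V)W with u = WY + b, a learned bias
   b, random orthogonal initialization from the run seed. Defaults:
   η = 0.1/ln(k·e), annealed ×0.9 whenever successive updates oppose
   each other, convergence at relative weight change < 1e-7, at most
   2000 iterations, and a bounded restart at halved η on weight blow-up.
   The rate/iteration budget was set for reliable convergence of the
   full-batch update: at an order of magnitude lower η the rotation does
   not converge within a few hundred iterations and components remain
   visibly entangled. Plain (not extended) Infomax is intentional: the
   logistic score separates super-Gaussian sources, and blob-like
   gray-matter patterns are strongly super-Gaussian. It is *unstable*
   for sub-Gaussian (e.g. uniform) sources — toy validations therefore
   use Laplace sources.
5. **Back-reconstruction and conventions.** S = WY and
   A = dewhitener·W⁻¹, so A·S equals the rank-k PCA reconstruction by
   construction (verified to ≤ 1e-6 relative Frobenius error; measured
   ~3e-16). Each source row is sign-fixed to positive skewness, scaled
   to unit variance (scale absorbed into A), and components are ordered
   by descending explained variance ‖A·ⱼ‖².
6. **Z-maps.** Each source row is scaled to zero mean / unit SD over the
   mask and thresholded at |Z| > 2.5 (two-sided by default; the display
   threshold is a convention, and a one-sided flag is provided). A
   standard-normal source survives at the 2·(1−Φ(2.5)) ≈ 0.0124 rate.

## ICASSO stability

ICA is repeated n_runs = 20 times with consecutive seeds
(base_seed … base_seed+19, recorded in the result and manifest). Pooled
sources are compared by absolute Pearson correlation, clustered by
average-linkage agglomeration on 1 − |r| cut at k clusters, and each
cluster is scored with

    Iq = mean intra-cluster |r| − mean member-to-non-member |r|.

The centrotype (member with maximal similarity to the rest of its
cluster; ties to the lowest run then component index) represents each
cluster, and final loadings are refit by least squares of the centered
data onto the centrotype sources, since centrotypes from different runs
need a consistent mixing matrix. Iq is reported raw and floored at 0 (a
negative value, possible when a cluster is less coherent than its
surroundings, is flagged with a warning).

**An Iq ceiling worth knowing about.** Even a perfectly re-estimated
decomposition does not reach Iq = 1: the extra-cluster term is the mean
absolute correlation between *different* sources, which is strictly
positive for non-negative blob patterns (for two disjoint maps it equals
μ₁μ₂/(σ₁σ₂)). On noiseless synthetic cohorts the intra-cluster
similarity is 1 to within 1e-10 while Iq saturates at ≈ 0.9957; the
corresponding acceptance check asserts the idealized value 1 ± 1e-6 and
documents this ceiling. At study-like SNR all clusters score Iq ≈ 0.995
(> 0.97), with exactly one member per run.

## Statistics on loadings

Per component: a two-sided variance-ratio F-test (larger variance in the
numerator) followed by Welch's unequal-variance t-test with
Welch–Satterthwaite (fractional) degrees of freedom, two-sided, with
Bonferroni familywise correction across the k components at α = 0.05.
Bonferroni is the simplest defensible familywise procedure for k = 8
weakly dependent tests. Clinical-score correlations are Pearson r within
the patient group only (controls have no scores), pairwise-complete over
missing values, Bonferroni-corrected over the m = 3 scores tested per
component. The confound check (loadings vs IQ) is a single uncorrected
correlation. Measured operating characteristics at the default design
(n = 50+32, k = 8): detection power ≈ 0.82–0.93 at d = 1.0; familywise
false-positive rate ≈ 0.03–0.06 under the global null (nominal 0.05).

## The synthetic-data generator

The generator emulates what the pipeline actually ingests — segmented,
normalized gray-matter concentration maps — not raw MRI. Subject i's
volume is

    V_i = baseline + Σⱼ A[i,j]·Sⱼ + scanner_offset(i) + ε,  clipped at 0.

* **Sources**: k truncated-Gaussian blobs (σ = radius/2, support edge
  continuous at distance = radius) placed on a max-spread lattice with
  pairwise center distance > 2·radius, so supports are disjoint and
  pairwise |r| < 0.05; centers get a small seed-driven jitter. Defaults:
  24³ grid of 2-mm voxels, radius min(grid)/8 = 3 voxels, amplitude 0.12
  in `simulate_study` (so blobs ride on a 0.5 baseline within a
  plausible [0,1] concentration range).
* **Loadings**: i.i.d. standard normal per component. The affected
  component's patient loadings get a ×1.5 variance inflation (so the
  Welch design is exercised against genuinely unequal variances) and a
  mean shift of d pooled SDs (default d = 1.0).
* **Scores**: patients only (total/social/stereotyped on ADOS-like
  scales 12±4, 8±3, 4±2), built as ρ·z(loading) + √(1−ρ²)·noise with
  ρ = 0.45 by default; controls' scores are missing. Scores are left
  continuous so that ρ = 1 with zero noise yields r = 1 exactly.
* **Demographics**: ages matched between groups (26 ± 5 y, clipped to
  18–39); IQ ~ N(110, 12) for controls vs N(100, 15) for patients. The
  planted IQ group gap means the IQ confound check is *not* a strict
  null: any group-different component inherits a small IQ correlation
  through the group variable, as in real cohorts.
* **Scanners**: two scanners, balanced within each group, optional
  additive intensity offset per scanner (a flat batch effect).
* **Noise**: i.i.d. Gaussian per voxel. The quoted SNR is global image
  SNR — grid-mean signal variance Σⱼ mean(Sⱼ²) over noise variance. (A
  per-voxel peak-amplitude definition would be misleading here: ICA's
  map-estimate noise is spread over the whole grid while the blob
  support is ~100 voxels, so "SNR 5" at the peak would make 0.9 spatial
  recovery unattainable; the global definition matches how image SNR is
  usually quoted.) Baseline 0.5 with amplitude-0.12 blobs puts the
  clip-at-zero event ≥ 4 noise SDs away, so clipping is a realistic but
  numerically negligible nonlinearity.

Everything (sources, loadings, scores, noise) derives from the single
design seed; a cohort is bit-reproducible, and the planted truth (maps,
loadings, affected component, design) is written alongside the volumes.

What the generator does **not** model: segmentation error, nonlinear
registration distortion, spatially correlated physiological noise,
non-Gaussian loading distributions, site effects beyond an additive
offset. Passing recovery tests on these cohorts therefore demonstrates
the correctness of the estimation machinery, not robustness to real
acquisition artifacts.

## Preprocessing conventions

Gaussian smoothing uses σ_vox = FWHM/(voxel·√(8 ln 2)) with reflective
boundaries (conserves total intensity for interior structure; an
impulse response matches the sampled Gaussian kernel to ≤ 1e-6 at the
peak). Anisotropic voxels are rejected rather than silently mishandled.
The analysis mask keeps voxels whose cohort-mean intensity exceeds a
threshold (default 0.05); in-mask voxels are linearized in C order, an
arbitrary but documented and run-stable convention that defines the
matrix columns. No per-subject intensity normalization or covariate
regression is applied before ICA.

## Pipeline and reproducibility

`run_pipeline` executes read → smooth → mask → matrix → (MDL | override)
→ ICASSO → Z-maps → cluster tables → group stats → correlations, writing
a flat key=value manifest with the full configuration, seeds, mask hash
and derived quantities. Reports are written with a fixed float format,
so a rerun with the same configuration is byte-identical. Stage failures
abort with the stage name and leave a `FAILED` marker beside the partial
outputs. Cluster extraction uses 26-connectivity by default (6/18
available), splits clusters by Z sign, and reports peaks in world mm via
the volume affine; anatomical labeling accepts any user-supplied integer
label volume (majority vote per cluster) — no atlas ships with the
package.

## Validation problem sizes

Recovery and stability validations run at the full study design (82
subjects, k = 8, 24³ grid) — ~1 s per decomposition, ~25 s per 20-run
ICASSO; power/size simulations use 100 and 200 cohorts at the
loading-matrix level, where the group statistics operate. Unit tests use
a compact 20-subject, k = 3, 16³ configuration.

## Known limitations

* The MDL variant assumes i.i.d. samples; on smoothed real data the
  estimated order is biased upward and should be overridden when an
  external estimate exists.
* Welch–Satterthwaite degrees of freedom are reported fractionally; no
  attempt is made to reproduce integer-df conventions of other software.
* No permutation-based FWE, partial correlations, or multi-covariate
  regression on loadings.
* Stability is initialization-only (no bootstrap resampling of
  subjects).
* FastICA/JADE are deliberately absent from the estimation path; plain
  Infomax is the method under study.
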