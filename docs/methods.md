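# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `fcdmap`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what the
code demonstrates.

## Surface model and smoothing

The cortex is a triangulated mesh; adjacency is exactly the edge set of the
triangle complex (no self-edges; degenerate triangles are rejected at
construction). Per-vertex overlays carry NaN outside the analysis mask and
masked vertices are excluded from every statistic.

Smoothing is iterated graph-Laplacian diffusion, `x ← x − c L x` with
`L = D − A`. Because `1ᵀL = 0`, each step preserves the overlay's total sum
exactly, and for `c·dᵢ ≤ 1` each step is a convex combination of neighbors,
so the diffusion maximum principle holds. Calibration to a requested
geodesic Gaussian FWHM uses the mesh's mean edge length *h*: one step adds
per-axis variance `c·d̄·h²/2` on a 2-D sheet, so `k` steps with
`c = 2σ²/(k·d̄·h²)` realize `σ = FWHM/√(8 ln 2)`; `k` is the smallest count
for which the required `c` is stable. The spec leaves open whether the
original smoothing was geodesic or spherical-registered; geodesic-on-mesh
was chosen because the synthetic surface *is* the registration domain. On
the default mesh (642 vertices, mean edge ≈ 7.5 mm) a 6 mm FWHM kernel is a
single mild diffusion step; smoothing is therefore validated against a
dense iterated-operator oracle rather than against an analytic sphere
kernel.

## Time-series QC

A volume is censored when the fraction of vertices whose deviation from
their temporal median exceeds *k*·MAD is above 5%, when framewise
displacement (sum of absolute backward differences of the six rigid-body
parameters, rotations as arc length on a 50 mm sphere) is strictly above
0.3 mm, and a subject is excluded when strictly more than 20% of volumes
are censored. The MAD multiplier deserves a note: read literally, "beyond
one MAD" is degenerate — by the definition of the median absolute
deviation, half of every continuous series exceeds it, so every volume
would be flagged. The default is therefore the detection rule of the
standard outlier counter, `k(T) = Φ⁻¹(1 − 0.001/T)·√(π/2)` (≈ 5.6 at
T = 250); `k = 1` remains available as an explicit argument. The MAD is
per-vertex by default (a global variant is exposed); zero-MAD vertices are
dropped from the fraction's denominator.

Nuisance regression is per-vertex OLS over retained time points against
intercept, linear drift, six motion parameters with first derivatives,
mean WM/CSF signals, and physiological series with derivatives. No temporal
band-pass filtering is applied anywhere. Censoring operators commute (the
final mask is a conjunction), and residuals are orthogonal to the design to
1e-8 (tested against a normal-equations oracle).

## FCD mapping

Global FCD counts strict exceedances r > 0.6 (ties excluded); correlations
are computed on censored, residualized series; constant-series vertices are
masked. The short-range count is the size, minus one, of the connected
component containing the seed in the mesh subgraph induced on the seed's
suprathreshold correlates — the growing algorithm. The seed is excluded
from its own count so that srFCD + lrFCD = global FCD holds as an exact
integer identity (the growing rule requires path vertices to correlate with
the *seed*, the literal reading; a pairwise-correlation variant would count
fewer). Two implementations exist and are tested to be identical: a
per-seed breadth-first search (the reference) and a simultaneous
propagation that advances all seeds at once through masked
boolean-matrix × sparse-adjacency products (the default; ~5× faster).
Blockwise computation of global FCD is bit-identical to the full-matrix
path. Maps are z-scored over the mask (mean 0, SD 1 before smoothing — a
constant map is rejected) and then smoothed, in that order.

## Vertexwise inference

One design matrix serves all vertices; a named term is tested by the
extra-sum-of-squares F against the design without that term's columns,
vectorized across vertices and verified to 1e-8 against scalar regression.
Continuous moderators are mean-centered before interactions are formed;
VIFs are computed for every non-intercept column and flagged at ≥ 10.

**Hierarchical correction.** Stage 1: statistics from *smoothed* maps are
Gaussianized through their p-values, thresholded at p < 0.001, and grouped
into connected components on the mesh. Cluster extent is measured in
resels — surface area over FWHM², with the effective FWHM estimated from
unit-normalized model residuals via the mean squared edge gradient
(`σ² = h²/(2⟨(Δu)²/h²⟩)`, FWHM = √(8 ln 2)·σ). Cluster-level FWE p-values
come from the 2-D Gaussian-field expected-cluster formulas: EC density
`ρ₂(u) = 4 ln 2 (2π)^(-3/2) u e^(-u²/2)`, exponential cluster-extent tail,
`p = 1 − exp(−E[m]·e^(−βk))`. Stage 2: Benjamini–Hochberg q-values over the
*unsmoothed* vertex p-values within each surviving cluster (q < 0.05). A
Freedman–Lane permutation test of the maximal cluster extent is implemented
both as the validation oracle and as a runtime alternative
(`method="permutation"`). Calibration is verified empirically: on 200 null
cohorts (40 subjects, 642 vertices) the fraction of runs with any surviving
cluster falls within [0.01, 0.10] at nominal 0.05. One caveat is inherent:
lowering p_vertex can *split* a surviving cluster into several, so
"stricter threshold, fewer clusters" holds for the suprathreshold vertex
set (which nests), not for the cluster count; the tests assert the nesting
form.

**Effect sizes.** Cohen's d at the cluster peak for group contrasts (for
group × sex, d is computed within the female stratum, where the planted
moderation acts); δ for continuous moderation = interaction coefficient ×
SD(moderator within the pre-diabetic group) / SD(model residuals) — the
source the study cites is not explicit, so δ is isolated in one function
and documented. BCa bootstrap CIs resample subjects (never vertices), with
bias correction from the bootstrap CDF at the point estimate and
acceleration from jackknife skewness; deterministic given a seed and
cross-checked against an independent BCa implementation.

**Bayes factors.** The JZS BF₁₀ compares the covariate-plus-predictor model
to the covariate-only null. Each model's marginal likelihood against the
intercept-only base uses the Zellner–Siow mixture-of-g prior
(g ~ InverseGamma(1/2, n·r²/2), Cauchy scale r = 0.354 on standardized
effects), a one-dimensional integral evaluated on the log scale by adaptive
quadrature after locating the mode; accuracy is held to < 1e-4 relative
against dense-grid trapezoid integration. BF₁₀ of a model against itself is
exactly 1, and the factor is invariant to affine rescaling of the outcome.
Findings are accepted under the triple criterion: frequentist p < 0.05,
BF₁₀ ≥ 3, and effect-size CI excluding zero.

**Cognition models.** Scores are standardized and Yeo-Johnson transformed
(MLE λ via profile likelihood); timing-based scores (TMT, Tower of London
seconds) are sign-flipped first so higher is always better. The model is a
full factorial of cluster-mean measure × moderators (group; group and sex;
group and HOMA) plus covariates; the highest-order interaction is tested,
and post-hoc simple slopes are reported per subgroup cell.

## Synthetic data: what it emulates, what it does not

The cohort generator reproduces the study conditions: 144 subjects (73
normoglycemia / 71 pre-diabetes; 79 females; subgroup sizes 39/34/40/31),
fasting glucose truncated-normal within the diagnostic bands (normo ≈
N(5.0, 0.3–0.4) below 5.6; pre-diabetes ≈ N(6.1, 0.4) in [5.6, 6.9]), and
all other biomarkers drawn around the published subgroup means and SDs,
with HOMA/CRF/MS/A-L derived by the package's own estimators. Height
(N(162, 6) / N(175, 7) cm by sex) and SRPA (uniform 1–5) have no published
values and are synthetic-only defaults.

BOLD data are 250-volume, TR = 2 s series on a 100 mm icosphere standing in
for a registered hemisphere pair, built from white-noise latent signals so
designed correlations have the closed form r = α²/(α² + σ²): connected
Voronoi patches share a patch signal at within-patch r = 0.7; eight
"connector" patches additionally share one weak global signal at pairwise
r = 0.58 (real cortex maintains distributed long-range coupling — and an
all-zero long-range map would be constant and unusable); the
"precuneus-like" hub pair has baseline coupling r = 0.50 (clearly
sub-threshold) rising to r = 0.7 in pre-diabetic females; the "mOFC-like"
patch's within-patch coupling drops by 0.12 per within-group HOMA SD across
pre-diabetic subjects. Nuisance structure (drift, random-walk motion with
occasional spikes, WM/CSF and pseudo-physiological signals) is added and
returned as the regressor table.

Not emulated: hemodynamic response shape, temporal autocorrelation
(latent signals are white, so effective degrees of freedom equal the
retained volume count — real BOLD has fewer), scanner artifacts, spatial
inhomogeneity of SNR, dropout, and anatomical geometry. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the generative model, not performance on real scanner data.

## Problem sizes and defaults

Defaults were chosen once as a realistic desk-scale study: 642-vertex
surface, 250 volumes, 24 patches, cohorts of 40 (null calibration, as a
typical small-study arm), 80 (planted-effect recovery, 20 per
group × sex cell) and 144 (full pipeline). The acceptance script runs 200
null simulations, 20 recovery replicates, and 1,000 bootstrap-coverage
replicates.

## Known limitations

- The RFT cluster p-value Gaussianizes the F field and uses Gaussian EC
  densities; the permutation alternative is the assumption-free fallback.
- Smoothness estimation assumes an approximately stationary residual field;
  the patch-structured generator violates stationarity mildly (calibration
  is nonetheless within the nominal band).
- The seed-FC positive mask threshold (one-sided p < 0.001 per group,
  union) is a documented choice; the study does not print one.
- HDL enters the MS score after mmol/l → mg/dl conversion (× 38.67),
  matching the printed 40/50 denominators' unit convention; a flag disables
  the conversion for mg/dl inputs.
- Insulin columns are treated as conventional units (mU/l); printed HOMA
  means are consistent with that reading, and an SI (pmol/l → /6) converter
  is provided for genuinely SI inputs.
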