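# Methods

`mcpain` reconstructs, as a reusable pipeline, the analysis chain that
predicts individual pain sensitivity from structural-MRI morphological
connectivity: per-ROI gray-matter intensity densities, symmetrised-KL
connectivity networks, SIMPLS partial least squares regression with
coefficient-ranked coarse-to-fine feature selection, and
leave-one-individual-out evaluation. This note records the model, the
numerical choices, and what the synthetic validation does and does not show.

## Morphological connectivity

For one participant, each ROI r contributes the vector of smoothed,
modulated gray-matter intensities at its atlas voxels. Its density p_r is
estimated by Gaussian KDE with Scott's-rule bandwidth
h = sd(x; ddof=1) · n^(−1/5). Connectivity between ROIs r and s is the
symmetrised Kullback–Leibler divergence (J-divergence)

    MC(r, s) = ∫ [p_r(x) − p_s(x)] · [log p_r(x) − log p_s(x)] dx,

written in product form so the integrand is pointwise non-negative and
exactly symmetric. The 90-ROI cerebral AAL parcellation gives a 90×90
symmetric matrix with zero diagonal; its strictly-lower-triangle
vectorisation (row-major) yields 4005 edge features per participant.

Numerical choices:

- **Shared grid per participant.** All of a participant's densities are
  evaluated on one uniform 512-point grid spanning the pooled sample range
  padded by 3 pooled bandwidths, so every pairwise integral uses a
  consistent support.
- **Density floor.** Densities are floored at ε = 10⁻¹² and renormalised to
  unit trapezoid integral; the KL integrand is then always finite. The
  floor is absolute, which has a measured consequence: when two ROI
  densities are strongly mismatched in spread (SD ratio ≳ 1.5), the narrow
  density's KDE tail hits the floor where the wide density still carries
  mass, inflating the estimate by up to ~30–40%. For moderate divergences
  (≲ 3) with comparable spreads, the estimator is accurate: at 5000 samples
  the bias is below ~3% and the per-edge sampling SD is ~5%. Tolerances in
  the tests reflect this: aggregate (median-over-edges) accuracy is held to
  5%, individual edges are not.
- **Quadrature.** Trapezoid on the uniform grid; claims are calibrated at
  512 points.
- **No similarity transform.** The divergence is used raw; an exp(−KL)
  similarity is available but off by default, since only the divergence
  itself is defined unambiguously.

Affine rescaling of all of a participant's intensities leaves the MC matrix
invariant (bandwidth, grid and densities are affine-equivariant) up to
floor effects; the suite verifies ≤10⁻³ drift in the moderate-divergence
regime.

## Regression model

The prediction model is y = Xα + E with one response (a pain threshold) and
K features (90 regional GMVs, 4005 MC edges, or their 4095-column
concatenation). α is computed by de Jong's SIMPLS on column-centered data;
features are not variance-scaled by default (MC edges share a scale; a
`standardize` flag exists for mixed feature sets and is recorded in the run
manifest). Components are nested, so one fit at the component cap yields
the coefficient path for every smaller count. The latent-component count is
chosen from the training coefficient of determination: smallest L with
R²(L) ≥ 0.95 by default, or the last L before the first R² increment below
0.01 in elbow mode. The default cap is min(K, N−1, 10). Weight-vector signs
are fixed (first nonzero element positive) so per-fold coefficient vectors
can be averaged meaningfully.

## Feature selection

Features are ranked by |α| (ties broken by ascending index) and the subset
size m* minimising a cross-validated error is found coarse-to-fine: scan
m = 1, 1+s, 2s+1, … for the first interval s (100 for MC-sized feature
sets, 10 for GMV), then rescan ±previous interval around the running best
at each finer interval, ending at 1. The search error is the MAE of
cross-validated predictions (MRAE and 1−r are available); ties in m* go to
the smallest m. The latent-component count is re-selected for every
candidate subset.

Two modes:

- **group_level** — the fold-averaged procedure: full LOO with all
  features, average the N per-fold coefficient vectors, rank once, search
  with a fresh LOO per candidate m. Because every participant's fold
  informs the chosen subset, the reported error is optimistic; this mode
  exists to reproduce the group-level protocol.
- **nested** (default) — within each training fold, rank on that fold only
  and search against an inner cross-validation confined to the training
  data (two repeats of 5-fold by default; inner LOO is available but ~12×
  slower), then predict the held-out participant with the fold's own
  subset. Reports per-fold subsets and their consensus (features selected
  in ≥50% of folds). This is the unbiased generalisation estimate; reports
  always name the mode.

## Evaluation

Leave-one-individual-out predictions are scored by MAE, MRAE and Pearson r.
MRAE refuses zero true values rather than adding an epsilon (near-zero
targets make it explode; the pain-sensitivity score can reach exactly 0 at
the cohort minimum, in which case MRAE is reported as unavailable). Error
sets of two feature sets are compared by a two-sided Wilcoxon rank-sum test
(Mann–Whitney U, normal approximation with tie correction); correlation
coefficients by a participant bootstrap of r_A − r_B (B = 2000, two-sided
percentile p), with a Williams-type dependent-correlation t-test available
as the alternative — no claim is made that either matches the original
analysis, whose test is unnamed. Selected MC edges are summarised by
unordered hemisphere-lobe pair counts (16 groups; top-k lists include
ties), and MC features can be cross-correlated with GMV under
Benjamini–Hochberg control.

The composite pain-sensitivity score is the arithmetic mean of the two
min-max-normalised thresholds; min-max (rather than z-scoring, which is
available behind a flag) is what bounds the score to [0, 1]. Higher score =
lower sensitivity.

## Synthetic cohorts

The study data are not public, so validation runs on generated cohorts with
closed-form ground truth. Participant i's ROI r intensities are
N(μ_ir, σ_ir²) with

    μ_ir = m_r + δ_ir,      δ_ir ~ N(0, τ²),         τ = 0.01 (default)
    σ_ir = s_r · exp(u_ir), u_ir ~ N(0, 0.18²),      s_r ∈ [0.08, 0.144]

so the true symmetric KL of every edge is the two-Gaussian closed form.
Default base means are equal across ROIs (0.5) and base SDs are geometric
across ROIs. Pain thresholds are planted as a sparse linear function of
cohort-standardised true MC edges plus Gaussian noise; laser thresholds are
affinely mapped onto the instrument range 1.75–4.25 J, cold thresholds
calibrated to cohort mean 9.59 s, SD 0.38 s. A `target_r2` option scales
the noise so the planted linear model explains a chosen variance fraction.
Everything is reproducible bit-for-bit from the seed.

Three generator decisions deserve explanation:

- **Individual variation lives in the SDs, not the means.** MC measures
  distribution shape, so the generator puts individual differences in
  regional intensity heterogeneity (the σ factors). This also makes
  regional GMV — which depends only on the means — carry no planted signal
  by construction, giving recovery experiments an honest negative control.
  Mean-carried variation is available (raise `subject_sd`, vary
  `roi_mean_base`) but leaks planted signal into GMV and, with equal base
  means, produces χ²-shaped edge distributions that any linear model
  struggles with.
- **Default planted weights are mixed-sign and graded** (+1.0, −1.1, +1.2,
  …). With a vertex-disjoint planted matching covering all ROIs and equal
  weights, the planted predictor is exactly exchangeable with any other
  perfect matching of the same ROIs — the "true" edges would be
  unidentifiable in principle. Mixed signs and magnitudes restore
  identifiability and mirror connections that raise or lower thresholds
  with varying effect sizes.
- **Laser thresholds use min–max range mapping.** Mapping the realized
  latent range onto 1.75–4.25 J guarantees the instrument range but places
  the cohort mean near the range midpoint (~3.0 J), higher than the ~2.6 J
  of a real staircase measurement; the correlation structure, which is what
  the pipeline consumes, is unaffected (affine maps preserve r).

What the synthetic cohorts do **not** emulate: voxel-level spatial
correlation and smoothing, registration error, non-Gaussian or multimodal
regional intensity distributions, cross-ROI covariance of individual
offsets (available via `offset_cov` but off by default), and any real
anatomical geography of effect locations. Passing recovery tests therefore
demonstrates that the estimator chain is correct and that the selection
machinery can find planted distributional signal — not that real pain
thresholds are predictable at any particular accuracy.

## Validation experiments and problem sizes

The reference recovery setting is 60 participants × 20 ROIs (190 MC
edges), 10 planted edges, planted-model R² ≈ 0.7, 1500 voxels per ROI,
replicated over 10 seeds; null calibration uses 20 pure-noise cohorts of
40 × 12 and 200 vectorised replicates of the two comparison tests. These
sizes make a full run of the suite a matter of minutes while leaving the
estimation regime (K ≫ N for MC) intact.

Honest expectations at that reference setting, measured with this package:
the LOO oracle that is *given* the 10 planted edges achieves r ≈ 0.7–0.85;
nested selection reaches r ≈ 0.2–0.8 depending on the seed (median ≈ 0.6),
and the consensus set recovers a median of ~7 of 10 planted edges. The gap to the
oracle is not an implementation defect: with N = 60, each planted edge's
marginal correlation with the response is ≈ √(0.7/10) ≈ 0.26 against a
null sampling SD of ≈ 0.13 across 180 correlated decoys, so reliably
ranking all ten planted edges above the noise is statistically impossible
at this sample size — selection instability under LOO at K ≫ N is the
expected behaviour, and the group-level mode's higher apparent accuracy is
exactly the optimism the nested mode exists to expose.

## Known limitations

- The density floor makes extreme divergences (tail-dominated pairs)
  systematically overestimated; comparisons *between* participants remain
  valid because the bias is edge-specific and stable.
- The AAL lobe assignment shipped with the package is coordinate-based and
  approximate; supply your own `roi_id,name,hemisphere,lobe` CSV to
  override it.
- `compare_correlations` is a generic bootstrap; it does not reproduce any
  particular published p-value.
- SIMPLS here is single-response (PLS1); multi-response prediction is out
  of scope, as are SVR or other regressors (the evaluation layer accepts
  any fit/predict pair, but only SIMPLS ships).
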