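# Methods

This note documents the statistical procedures implemented in `uromet`,
the design choices made where several defensible options existed, and what
the synthetic test-bed does and does not establish about real data.

## Synthetic paired cohort

A metabolite is a set of peaks (center ppm, relative height, FWHM); a
spectrum is the concentration-weighted sum of height-normalized Lorentzian
lineshapes (a Gaussian option exists behind `lineshape=`), plus a flat
baseline and i.i.d. Gaussian noise, on a 0.5–9.5 ppm axis of 2048 points —
small enough for fast tests, dense enough that binning is nontrivial.
Chemical-shift jitter is drawn once per metabolite per sample and applied
to all of that metabolite's peaks, mimicking the pH-driven whole-multiplet
drift that buffered acquisition only partially controls.

Defaults (`CohortConfig`): 6 subjects × 2 timepoints; subject-level
log-concentration SD 0.25; jitter SD 0.004 ppm; baseline 0.01; noise SD
0.02 (intensity units in which a unit concentration gives a unit peak
height); three planted biomarkers with log-fold timepoint effects −1.0
(dopamine-like), +0.9 (Sumiki's-acid-like), −0.8 (caffeine-like). A
0–100 functional-independence score is generated as
`post = clip(pre + intercept + Σ βᵢ zᵢ + ε)` with `zᵢ` the standardized
log initial level of biomarker *i* — linear coupling with Gaussian noise,
because Pearson correlation is the downstream estimand and linear coupling
makes its recovery well-posed. Effect sizes are chosen for testability:
the source literature for this design reports no real effect sizes.

Peak positions in the bundled library are illustrative toys, not
literature chemical shifts. Each clinically coupled biomarker has at least
one isolated peak; this matters, because a biomarker whose every multiplet
overlaps static neighbours has its *initial-level* bin correlation
attenuated (the *delta* cancels the neighbours and is immune), and the
generator is required to make the correlation analysis recoverable.

`planted_bin_matrix` is a second, bin-level generator used for the
variable-selection studies: 500 unit-variance bins over 30 subjects × 2
timepoints, a subject random effect (SD 0.5), and a 3-bin planted panel
shifted by 1.2 within-class SDs at the second timepoint. The planted bins
share a zero-sum noise component, so each is individually a moderate
discriminator while the full panel separates the classes almost perfectly —
the complementarity a real multi-metabolite panel shows when its members
report on one latent process. The sample size is deliberately larger than
the clinical cohort: at 12 samples and 500 bins, chance produces noise
bins whose in-sample discrimination rivals any plausible real effect, so
exact panel recovery is not statistically identifiable at that scale and a
recovery guarantee would be meaningless.

What passing tests show — and do not show. The generator emulates
positional noise, subject-level confounding, compositional coupling
through total-area normalization, and noise floors; it does not emulate
baseline distortion, phasing errors, peak-shape asymmetry, water/urea
resonances (two fixed exclusion windows stand in for them), missing
timepoints, or diet-driven metabolite variation. Recovery results
therefore validate the *pipeline logic*, not field performance on real
spectra.

## Spectral processing

Alignment is recursive and segment-wise: a segment is shifted by the
integer-point offset maximizing Pearson correlation with the reference
within ±`max_shift` (0.03 ppm default), ties broken toward the smaller
|shift|; segments recurse by splitting at the lowest-intensity interior
point until shorter than 2·`min_segment` (64 points) or until the best
correlation gain falls below `tol` (1e-3). Gaps are filled with edge
values, which bounds the intensity change by the padding contribution
(asserted ≤ 1% on synthetic peaks). Segments whose best correlation stays
below `min_corr` (0.6) are left unshifted and flagged unalignable — the
contract for displacements beyond the search window. The reference is the
cohort mean, recomputed once after a first alignment pass. Smoothing
throughout is a moving average (11 points default) rather than a wavelet
transform: simpler, deterministic, and serving the same intent of placing
boundaries at troughs.

Adaptive binning places boundaries at interior local minima of the
smoothed mean spectrum (strict on the left, permissive on the right, so a
flat trace yields no boundaries). Bins whose smoothed maximum stays below
`noise_threshold` (default: median + 3·MAD of the smoothed trace) are
noise bins; contiguous noise bins coalesce. Bins narrower than `min_width`
(0.02 ppm) merge across their weaker (higher-valued) trough, preferring a
neighbour of the same noise classification. Boundaries snap to grid
points and adjacent bins share their boundary point, which makes
trapezoidal integrals exactly additive under bin splitting. On the default
synthetic cohort this yields ~50 bins; the bin count of any given study is
data-dependent, not a contract, and the coalescing of flat baseline into
single noise bins is why the toy cohort produces far fewer bins than a
clinical spectrum would.

## Preprocessing

Fixed order: total-area normalization over retained bins (noise, manual
and water/urea-region exclusions dropped; every row then sums to 1 and
within-sample ratios are preserved) → log₁₀(x + ε) with ε = half the
smallest positive matrix value, recorded for provenance → pareto scaling
with the sample (n−1) SD; zero-variance columns are dropped and reported.
The row-normalized matrix is kept alongside the scaled one because the
correlation analysis operates on normalized concentrations per timepoint,
not on pareto-scaled values.

## Univariate screen

Normality is assessed on the paired differences — the quantity whose
distribution the paired *t*-test actually assumes — with Shapiro-Wilk at
`alpha_normality` = 0.05. Non-normal bins go to the Wilcoxon signed-rank
test; its two-sided p-value is exact for n ≤ 25 via a dynamic-programming
convolution over doubled midranks (identical to 2ⁿ sign-flip enumeration,
ties included; zeros are discarded). "Paired Wilcoxon-Mann-Whitney" is a
contradiction in terms — Mann-Whitney is an unpaired test — and is
resolved here as the signed-rank test on paired differences, consistent
with the paired design. Constant differences are reported untestable
rather than forced through either route. No multiplicity correction is
applied at this stage: the screen's raw significant set feeds the
multivariate stage, and only the correlation analysis applies Bonferroni.

## OPLS-DA, DCV and permutation testing

Labels are encoded −1/+1 and centered. Orthogonal components are extracted
by the standard single-y O-PLS step (w ∝ Xᵀy; w_orth ∝ p − (wᵀp)w; deflate
X by t_orth p_orthᵀ), then one predictive component is fitted; with zero
orthogonal components the model is exactly single-component PLS1-DA.
R²Y is the training fraction of label variance explained. Q² comes from
double cross-validation: stratified ten-fold outer and inner loops that
collapse to leave-one-out whenever a class is smaller than the fold count
(so every sample is held out at least once), with the inner loop choosing
the number of orthogonal components (0–3; more is unstable at a dozen
samples) by inner prediction error; Q² = 1 − PRESS/TSS over pooled outer
predictions. Note that pooled-PRESS Q² is not mathematically bounded by
the fixed-complexity training R²Y and can exceed it marginally on
near-perfectly separated data. Permutation p-values use
(#{perm ≥ obs} + 1)/(n_perm + 1) with 2000 permutations by default
(pipeline Q² permutations run at one tenth of `n_perm` — the DCV inside
each permutation makes the full count two orders of magnitude more
expensive than the R²Y statistic for no change in the conclusion at the
scales involved). Heat-map ordering uses Ward linkage on Euclidean
distances for both axes, the defaults of the standard metabolomics
tooling.

## VIAVC

Each round draws `n_rows` (500) Bernoulli(0.5) bin masks (all-zero rows
redrawn), scores every mask's subset by pooled cross-validated
single-component PLS1-DA decision values, and computes per-bin importance
as the mean-AUC difference between masks including and excluding the bin.
Rounds iterate by halving: the bottom half of the ranking is eliminated
and the matrix redrawn over the survivors until at most `min_final_bins`
(24) remain — a single global round over hundreds of bins dilutes any
bin's marginal contribution below detectability, while the iterative
reduction concentrates the resampling budget the way the original
procedure intends (`n_iterations=1` restores single-round behaviour). The
final ranking lists survivors by final-round importance, then earlier
casualties by elimination round; the "F-ranked" head (19 bins by default)
feeds the correlation screen. The best subset is the nested head
(top-1, top-2, …, top-`max_k`) with maximal cross-validated AUC, ties
broken toward fewer bins; the reported best-subset AUC is floored at 0.5
by orientation convention, with the raw value retained.

A bin is categorized *significant* only if (a) the one-sided Mann-Whitney
test on its include/exclude AUC populations clears a Bonferroni threshold
α/n_bins, and (b) its importance is an outlier of the across-bin
importance distribution (robust z from median/MAD at the same Bonferroni
level). The second condition exists because the first alone has power
growing without bound in `n_rows` against fixed in-dataset quirks: a
dataset with shuffled labels still contains bins that genuinely
discriminate those labels *in that sample*, and only the across-bin
exchangeability argument — under a global null all bins are alike —
provides a defensible reference. Even so, family-wise control under the
null is approximate, not exact; exact control would require
label-permutation recalibration of every round at a ~40× cost.

The classifier inside VIAVC is single-component PLS1-DA, consistent with
the OPLS-DA core. Because the PLS weights re-orient with the labels,
cross-validated subset AUC is *invariant* under a label flip; the
1 − AUC complement applies only to fixed score vectors.

## Biomarker evaluation

AUC is the normalized Mann-Whitney U with ties counted one half, which
equals the area under the empirical ROC step curve and is invariant under
strictly monotone score transforms. Confidence intervals are stratified
percentile bootstrap (2000 resamples; within-class resampling keeps both
classes present). Panel accuracy evaluates nested panel heads under
cross-validation with the decision threshold set on each training fold at
the Youden point (midpoint grid between sorted training scores, ties to
the lowest threshold); the paper-style 92% → 100% two-then-three-bin
pattern is reproduced by a deterministic 12-sample construction in which
two redundant bins miss one sample and a third, stronger bin resolves it.

## Clinical correlation

The SCIM percent difference is 100·(post − pre)/((post + pre)/2), exactly
antisymmetric under swapping pre and post; undefined when both scores are
zero. The metabolite delta defaults to *initial − post*, following the
source convention literally even though it inverts the usual sign; the
opposite convention is available. Both predictor families (initial level,
delta) are Pearson-correlated with the percent difference using the exact
t-transform (df = n − 2), and each family is Bonferroni-corrected over the
same tested-bin list (α/19 for the default F-ranked head); a pooled
2×19-test correction is available behind `pooled=True`. Zero-variance
predictors yield an undefined R and are never significant. Flag counts
are non-increasing in the tested-list length only among a fixed bin
subset — a longer list tightens the threshold but also adds new
candidates.

## Pathway analysis

Over-representation is the exact hypergeometric upper tail P(X ≥ k) for k
hits in a K-compound pathway when n significant compounds are drawn from
an N-compound background; significant compounds missing from the
background are dropped with a warning (identifier-mapping misses, not
errors). Topology impact is the sum of matched-node betweenness
centralities divided by the pathway total, falling back to degree
centrality when all betweenness vanishes (edge pairs, edgeless sets) and
to zero when both vanish. The bundled library is a synthetic fixture of
ten small pathway graphs over the peak library's compound identifiers — a
live pathway database would be neither versionable nor testable offline —
and its purine-metabolism-like pathway is deliberately enriched in the
default planted biomarkers so end-to-end recovery is checkable. No
multiple-testing correction is applied to pathway p-values by default
(matching the raw-p reporting convention of the interactive tools this
replaces); Holm adjustment is available.

## Pipeline and reproducibility

Stage order: spectral processing → preprocessing → univariate screen →
VIAVC → multivariate models on the *union* of univariate-significant bins
and the VIAVC best subset → ROC of the best subset → correlations on the
top F-ranked bins → pathway screen on the union's compounds. Every stage
reads and writes only documented CSV/JSON artifacts, logs stage, seed and
parameter hash, and registers in a manifest; all stage seeds derive from
the single config seed, and re-running a deleted run directory reproduces
it byte-identically.

## Problem sizes used in tests

The suite runs the spectral cohort at 6 subjects (30 for correlation
recovery), the bin-level selection studies at 500 bins × 60 samples over
20 seeds, Monte-Carlo calibrations at 100–200 replicates, and permutation
calibrations at 19 permutations × 200 replicates; these sizes make the
distributional assertions stable at conventional test tolerances while
keeping the full suite in the low minutes on one CPU.

## Known limitations

- Alignment searches integer-point shifts only; sub-point displacement is
  not interpolated.
- The adaptive binner has no concept of peak shape, only troughs; strongly
  overlapped multiplets merge into single bins.
- OPLS-DA supports exactly two classes and a single predictive component;
  no S-plots, no ≥3-class variant.
- The VIAVC significant category is approximately, not exactly,
  null-calibrated (see above).
- Q² of pooled-PRESS form can marginally exceed training R²Y on separable
  data; the two are reported independently rather than clamped.
- The pathway fixture is a toy: impact values are meaningful relative to
  the fixture's own topology only.
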