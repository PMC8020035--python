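# uromet

Paired-design ¹H NMR urinary metabolomics, packaged as a tested, reusable
pipeline. The target study design is the small clinical cohort sampled at
two timepoints per subject — for example urine collected from spinal-cord-
injury (SCI) patients shortly after injury and again months later — where
the questions are: *do the metabolic profiles change between timepoints,
which spectral features drive the change, and do metabolite levels track a
clinical recovery score?*

`uromet` covers the full post-acquisition workflow:

1. **Spectral processing** — recursive segment-wise alignment of each
   spectrum to the cohort mean, adaptive binning (boundaries at troughs of
   the smoothed mean spectrum), trapezoidal bin integration, and a
   reproducible merge/split/exclude edit script in place of interactive bin
   curation.
2. **Preprocessing** — normalization to the total metabolome (water and
   urea regions excluded), log₁₀ with a half-minimum offset, and pareto
   scaling (x ↦ (x − x̄)/√s), each an sklearn-style transformer.
3. **Univariate screen** — per bin, Shapiro-Wilk on the within-subject
   differences routes to a paired *t*-test or an exact Wilcoxon signed-rank
   test (dynamic-programming null, ties handled).
4. **Multivariate models** — PCA, Ward hierarchical clustering for heat-map
   ordering, and OPLS-DA: y-orthogonal variation is removed before a single
   predictive PLS component is fitted; R²Y, double ten-fold cross-validated
   Q² = 1 − PRESS/TSS, and permutation p-values
   p = (#{perm ≥ obs} + 1)/(n_perm + 1) summarize the fit.
5. **VIAVC variable selection** — variable importance from random variable
   combinations: Bernoulli bin-subset resampling, cross-validated PLS1-DA
   AUC per subset, per-bin importance = mean AUC with the bin − mean AUC
   without it, iterative halving to an F-ranked list, and a nested
   best-subset search maximizing cross-validated AUC.
6. **Biomarker evaluation** — tie-aware ROC/AUC (Mann-Whitney form),
   stratified percentile-bootstrap confidence intervals, and nested-panel
   classification accuracy with training-fold Youden thresholds.
7. **Clinical correlation** — the symmetric SCIM percent difference
   100·(post − pre)/((post + pre)/2), metabolite deltas, and Pearson
   correlations of both initial levels and deltas against recovery,
   Bonferroni-corrected over the top F-ranked bins (α/19 by default).
8. **Pathway analysis** — exact hypergeometric over-representation and
   relative-betweenness-centrality topology impact over a bundled
   synthetic pathway-graph fixture.

Because raw clinical NMR spectra are rarely shareable, the package ships a
first-class synthetic-cohort generator (`uromet.simulate`): Lorentzian peak
libraries, per-metabolite chemical-shift jitter, planted between-timepoint
log-fold effects, and clinical scores linearly coupled to designated
biomarkers — so every stage is testable against a recorded ground truth.

## Worked example

```
$ uromet simulate --out demo/cohort --seed 7
wrote 12 spectra and clinical.csv to demo/cohort

$ uromet run --spectra demo/cohort --clinical demo/cohort/clinical.csv \
             --out demo/run --n-perm 200 --seed 7
uromet run summary
==================
seed: 7  params: 1bd0bb8cd685
univariate significant bins: 14
VIAVC best subset: ['bin_025'] (AUC 1.000)
OPLS-DA: R2Y 0.985 (p 0.0100), Q2 0.955 (p 0.0476)
ROC AUC 1.000 (95% CI 1.000-1.000)
correlations: 0 significant of 19 tested x2
top pathway: pw02
```

Reading the output: 14 of the ~50 adaptive bins differ significantly
between the two timepoints before multiplicity correction; VIAVC finds that
a single bin already separates the timepoints perfectly under
cross-validation (the planted effects in the default cohort are strong);
the OPLS-DA on the union of significant bins explains 98.5% of the
class-label variance with a cross-validated Q² of 0.955, and label
permutation shows both are far from chance. No clinical correlation
survives the Bonferroni screen at n = 6 subjects — the expected outcome at
this sample size; the correlation machinery is exercised with adequate
power (n = 30) in the test suite. Every stage writes its CSV/JSON artifacts
plus a provenance manifest to `demo/run/`, and stages can be re-run
individually (`uromet process/analyze/correlate/pathway/report`).

The library API mirrors scikit-learn where the operations are
fit/transform-shaped — `OPLSDA`, `VIAVCSelector`, `ParetoScaler`,
`Log10Shift`, `TotalAreaNormalizer` all compose with sklearn pipelines —
with thin module-level functions (`fit_oplsda`, `rank_variables`,
`pareto_scale`, ...) over them.

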