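# Methods

This note documents the models behind `methylpanel`, the parameter
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the judgment calls made where the underlying
procedures are ambiguous.

## Discovery stage

**DMP calling.** For each probe we compute Δβ = mean β(tumor) − mean
β(normal), the normal-group mean β, and a two-sided two-sample t-test.
The default test is Welch (unequal variances): tissue discovery cohorts
of this kind are highly unbalanced (hundreds of tumors against a few
dozen adjacent normals), where the classical equal-variance test is
anticonservative; `equal_var=True` restores the classical test. P-values
are corrected across all probes by the Benjamini–Hochberg step-up
procedure (delegated to `statsmodels.multipletests(method="fdr_bh")`,
with the step-up definition enumerated independently in the test suite).
A probe is a DMP when |Δβ| ≥ 0.2, normal mean β ≤ 0.1 and q ≤ 0.01.
The control-β filter implicitly restricts to tumor-hypermethylated
markers — exactly the kind usable in a methylation-specific PCR assay —
so no hypomethylation branch exists.

Degenerate probes: when both groups have zero variance, the t-statistic
is undefined. We set p = 1 when the group means are also equal (no
evidence of any difference) and p = 0 when they differ (two disjoint
point masses — infinitely strong evidence). Without the second clause a
noiseless fully-shifted probe would absurdly be declared null.

**DEG calling** applies the same test to log₂(x + 1) expression; the +1
keeps zero RSEM values finite. Significance is by FDR alone.

**Correlation.** Spearman, Pearson and Kendall coefficients per gene
across shared samples. When several probes map to one gene the probe
with the largest |Δβ| represents it (largest variance when no labels
are available); zero-variance vectors are flagged `degenerate` with NaN
coefficients rather than silently dropped.

**Candidate selection** intersects DMP-significant genes,
DEG-significant genes and genes with negative Spearman correlation —
the biologically coherent pattern of promoter hypermethylation
silencing its gene.

**LASSO weight scoring** (`LassoStabilitySelector`). Each repeat draws
a stratified 70/30 split, fits `LogisticRegressionCV(penalty="l1",
solver="liblinear")` on the training part with the penalty chosen by
5-fold internal cross-validation over 10 candidate strengths, counts
features with nonzero coefficients as selected, and records held-out
sensitivity/specificity at probability 0.5. Features are standardized
on each training split before fitting (the glmnet convention): an L1
penalty applied across unequally scaled features selects by scale, not
by signal. Genes are ranked by selection frequency; ties break by mean
|coefficient| and then input order, and both quantities are reported so
a user can apply a different tie policy. The default 1000 repeats match
the weight-scoring design; the acceptance checks use 100, which is
already far past the point where the frequency ranking stabilizes on
the synthetic cohorts. Defaults of 5 folds and 10 penalty values are
implementation choices; the source procedure states none. Splits are
stratified so both classes are always present; the degenerate split is
resampled (it essentially cannot occur under stratification).

Discovery feature matrices for the weight scoring use each candidate
gene's representative-probe beta values: the markers being selected are
methylation markers, and beta values are what the downstream assay will
measure.

## Call algorithms

ΔCT is defined as marker CT minus the same well's ACTB CT; ACTB is the
only internal control in the assay, and a well is one reaction, so the
two-marker rule of the balancing algorithm is evaluated strictly within
one well. "In a single test" is read as *at least one of the two
wells*; "for each well" as *both wells*. Marker positivity is strict
(`CT < cutoff`, per "smaller than"); internal-control validity is
non-strict (ACTB CT ≤ 40). A sample whose wells include any invalid
well is INVALID and listed for retest; it is excluded from metrics with
a retained count rather than re-drawn. Undetermined channels are NaN in
memory — any comparison with a finite cutoff is false, so an
undetermined channel can never satisfy a rule — and the literal string
`Undetermined` on disk, matching qPCR export conventions; encoding the
sentinel as a large number would risk accidental threshold passes.

The balancing algorithm is the package default: its cutoffs
(45/38/40) are the ones the per-gene headline analyses use. Removing
the mALX4 channel (`include_alx4=False`) blanks that channel before
calling; since every rule is monotone in channel positivity, removal
can only delete positives — sensitivity and PL detection can only fall
and specificity only rise, which the test suite verifies as an
invariant on random cohorts.

## Performance stage

**Accuracy excludes PL subjects** — (CRC positives + NED negatives) /
(n_CRC + n_NED). This differs from the usual all-subject accuracy and
is deliberate: an adenoma called either way is not obviously an error,
so screening assays report PL detection separately. The denominators
make the convention explicit in every output.

**Confidence intervals** default to the Wilson score interval with
continuity correction (the VassarStats convention; Newcombe 1998,
method 4), with plain Wilson, Clopper–Pearson and Wald selectable.
Simulated coverage at p ∈ {0.1, 0.5, 0.9}, n ∈ {40, 75, 171} stays
above 93% at nominal 95%. Printed CIs from assay reports are matched
only approximately by any closed form, so CIs are treated as
descriptive, not as exact targets.

**Youden cutoffs** maximize sensitivity + specificity over midpoints of
consecutive distinct scores (plus open ends); ties break toward the
more specific threshold — for CT semantics, the lower cutoff — so that
a reported cutoff never calls more subjects positive than an equally
good alternative.

**Repeated-split logistic ROC.** Univariate logistic regression per
marker on 70/30 stratified splits, 100 repeats by default, undetermined
CTs imputed to a ceiling (default 50, above any observable CT; the
ceiling is configurable and results are insensitive to it as long as it
exceeds every finite CT). The model uses a very weak L2 ridge
(C = 10⁶) so perfectly separating markers fit finitely instead of
diverging. The combined any-marker-positive rule is scored both with
per-gene Youden cutoffs learned on the training split and with a fixed
cutoff set, since either convention is defensible.

**Cohen's κ** for duplicate concordance is computed on single-well
positivity (each well judged in isolation by the per-well part of the
algorithm's rule). The CI uses the Fleiss–Cohen–Everitt large-sample
variance and the p-value the null-variance normal approximation.
Published κ intervals for this kind of data are sometimes implausibly
narrow for the cohort size; we report the standard asymptotic interval
and make no attempt to match non-reproducible widths.

**Sample-size planning** returns the smallest n whose CI width at the
expected proportion is within the requested width (Wald, Wilson or
exact). It is a planning tool, not a reproduction of any commercial
package's output: e.g. expected sensitivity 0.83 with full width 0.08
gives n = 339 under Wald.

## Synthetic generators

**Tissue cohort.** Beta values are drawn from Beta distributions
parameterized by mean m and concentration c as Beta(mc, (1−m)c) —
bounded support matching beta-value semantics — through a Gaussian
copula. Informative probes have normal-group mean at
`control_beta_level` (default 0.05) and tumor mean shifted by
`delta_beta_effect` (default 0.45), so planted probes pass the DMP
filter in expectation; null probes share one mean per probe
(uniform on [0.05, 0.95]) across both groups. Expression is log-normal
around a per-gene baseline (log₂ baseline uniform on [6, 12], SD 1 in
log₂ units); informative genes get a `expr_effect_log2fc` shift
(default −2) in tumors and share the probe's latent normal variable
with weight `meth_expr_coupling` (default −0.7), which produces a
negative methylation–expression correlation of roughly that magnitude.
Default cohort sizes (396 tumors / 35 normals) mirror a 450K discovery
cohort; tests and acceptance runs use scaled-down cohorts (60/30,
200–1000 probes), sizes at which the planted effects are still
recovered essentially perfectly.

What the generator does *not* emulate: probe-probe correlation along
CpG islands, batch and purity effects, matched-pair structure of
adjacent normals (tests are unpaired two-sample accordingly), and
heavy-tailed expression dispersion. Passing tests therefore demonstrate
the pipeline's statistical machinery, not its behavior on the full
messiness of array data.

**Plasma qPCR cohort.** Each subject contributes `n_wells` (default 2)
independent wells; each marker channel of each well is
methylation-positive with a per-group per-gene probability, drawing
CT ~ Normal per gene (defaults mSEPT9 (38, 2.5), mALX4 (37.5, 1.5),
mSDC2 (38, 2.0), clipped positive) when positive and `Undetermined`
otherwise; ACTB ~ Normal(29, 1.5) per well, pushed above the validity
cutoff with probability `invalid_rate`. No distributional information
about real CT values is available, so these distributions are free
choices, placed where the call rules' thresholds are actually exercised
(detected channels usually positive at 45-grade cutoffs, roughly
half-positive at 38-grade cutoffs, ΔCT near the 10-limit).

The `a2_like_spec` preset (75 CRC / 40 PL / 171 NED) carries per-group
detection probabilities hand-tuned so that balancing-algorithm calls on
a large simulated cohort land near the assay operating point recorded
in `A2_OPERATING_POINT` (sensitivity 0.827, specificity 0.901, PL
detection 0.550). The probabilities are calibration artifacts of this
generator — approximations, not measured per-well detection rates. The
well-level detection model is also independent across wells and genes,
which understates the within-subject correlation real duplicates show;
the preset's duplicate κ (≈ 0.3–0.4) is therefore in the moderate range
but not a measurement of assay concordance.

## Known limitations

- Stratum-standardized rates (age/gender standardization) are not
  computed — standardization weights for such tables are generally
  unpublished — only crude per-stratum rates with exact pooling.
- The discovery chain treats probes independently; no region-level
  (DMR) aggregation.
- INVALID samples are excluded with a logged count; no retest workflow
  is modeled.
- The per-gene CT cutoff sets are taken as given; the package can
  re-derive Youden cutoffs from data but does not attempt to reproduce
  the provenance of the fixed 40.67/36.8/36.23 set.
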