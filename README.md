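# methylpanel

Analysis pipeline for plasma cell-free-DNA methylation screening panels
in colorectal cancer (CRC), built around a three-marker multiplex
methylation-specific qPCR assay (mSEPT9, mALX4, mSDC2 with an ACTB
internal control, two wells per subject).

The package covers the three computational stages such a screening
study needs:

1. **Biomarker discovery** from a tumor/normal tissue cohort
   (Illumina 450K-style beta values plus RSEM-scale expression):
   differentially methylated positions (|Δβ| ≥ 0.2, normal-group mean
   β ≤ 0.1, Benjamini–Hochberg FDR ≤ 0.01, Welch t-test), differentially
   expressed genes on log₂(x + 1), Spearman/Pearson/Kendall
   methylation–expression correlation, candidate intersection
   (DMP ∧ DEG ∧ ρ_Spearman < 0), and a LASSO weight-scoring system:
   L1-penalized logistic regression refitted over repeated stratified
   70/30 splits (1000 by default), ranking genes by the frequency with
   which their coefficient is nonzero.
2. **Duplicate-well call algorithms** turning the two wells' CT values
   into one POSITIVE/NEGATIVE/INVALID result per subject:
   - *balancing* — positive if every well has a marker below 45/38/40,
     or mALX4 < 38 in any single well, or two markers in one well have
     CT < 40 with each ΔCT (marker − ACTB) < 10;
   - *one-half* — positive if any single well has a marker below
     45/38/43 with ΔCT < 15;
   - *two-thirds* — positive if both wells each have a marker below
     40.67/36.8/36.23.
   All require the internal control valid (ACTB CT ≤ 40) in both wells;
   marker positivity is strict (`CT < cutoff`); an `Undetermined`
   channel never passes.
3. **Diagnostic performance**: sensitivity (CRC), specificity (NED),
   precancerous-lesion (PL) detection rate, and accuracy over
   CRC + NED only, each with Wilson continuity-corrected 95% CIs;
   stratified detection-rate tables with exact pooling; Youden
   (max sensitivity + specificity) cutoff selection; repeated-split
   univariate logistic ROC/AUC; Cohen's κ for duplicate-well
   concordance; and CI-width sample-size planning.

Because raw per-subject clinical data for such assays are rarely
deposited, the package ships first-class synthetic generators — a
tissue cohort with planted hypermethylated markers coupled negatively
to expression, and a plasma qPCR cohort with group-specific per-gene
detection probabilities — so the whole chain is testable end to end.

## Worked example

Simulate the default plasma cohort (75 CRC / 40 PL / 171 NED subjects,
two wells each), call it with the balancing algorithm, and summarize:

```python
from methylpanel.simulate import a2_like_spec, simulate_qpcr_cohort
from methylpanel.calling import call_cohort
from methylpanel.performance import confusion_summary

wells = simulate_qpcr_cohort(a2_like_spec(seed=1))        # 572 well rows
calls = call_cohort(wells, "balancing")
print(confusion_summary(calls).to_frame().to_string(index=False))
```

```
      metric  percent  successes   n  ci_low_percent  ci_high_percent
 sensitivity     82.7         62  75            71.8             90.1
 specificity     90.1        154 171            84.3             93.9
pl_detection     52.5         21  40            36.3             68.2
    accuracy     87.8        216 246            82.9             91.5
```

62 of 75 cancer subjects and 21 of 40 adenoma subjects are called
positive while 154 of 171 disease-free subjects are called negative;
accuracy pools the CRC and NED groups only (216/246), since PL
detection is reported separately. The same stages are available from
the shell:

```bash
methylpanel simulate qpcr --out sim --seed 1
methylpanel call --wells sim/wells.tsv --algorithm balancing --out calls.tsv
methylpanel evaluate --calls calls.tsv --report report/
methylpanel run --out full_run/          # simulate → discover → call → evaluate
```

`DuplicateWellCaller`, `DmpSelector`, `DegSelector` and
`LassoStabilitySelector` follow scikit-learn estimator conventions
(`fit`/`predict`/`transform`, `get_params`, trailing-underscore fitted
attributes) and compose with sklearn tooling.

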