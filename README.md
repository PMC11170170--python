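# magescreen

Analytics for biomarker screening of MAGE-A4-targeted TCR T cell therapies.

Engineered T cell receptor (TCR) therapies recognise a tumor peptide only
when it is presented by a specific HLA molecule, so trial eligibility rests
on two biomarkers determined at screening: the patient's HLA-A genotype and
tumor MAGE-A4 expression by immunohistochemistry (IHC). `magescreen`
implements the analysis side of such a screening program as a tested Python
library:

* **HLA eligibility** — WHO-nomenclature allele parsing (`A*02:01:01:02N`),
  genotype-list strings with ambiguity alternatives (`a+b|c+d`), P-group
  equivalence (alleles identical over the peptide-binding α1/α2 domains),
  and the eligibility rule *at least one inclusion allele
  (A\*02:01P/02:02P/02:03P/02:06P) and no exclusion allele (A\*02:05P)*.
  Ambiguous calls whose candidates disagree are reported indeterminate.
  Cohort summaries attribute each eligible patient to the inclusion
  allele(s) responsible (A\*02:01P vs the rarer alleles that extend
  eligibility in non-White populations).
* **Typing concordance** — validation of an HLA assay against reference
  genotypes, with one-sided exact lower confidence bounds on the concordance
  proportion *p*: Clopper–Pearson (the α-quantile of Beta(x, n−x+1), equal
  to α^(1/n) when x = n) and the Wilson score bound
  (p̂ + z²/2n − z·√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n), both compared to a
  95% acceptance threshold.
* **IHC scoring** — the P score (percent of tumor cells staining at ≥ 2+
  intensity), positivity at the P ≥ 30% cutoff, prevalence by tumor type /
  histology / tissue location / archival-time stratum, paired
  primary-vs-metastatic agreement, and inter-reader percent agreement.
* **Potency classification** — three-parameter log-logistic fits
  y = d / (1 + exp(b(ln x − ln e))) of cell-ELISA dose-response curves with
  the lower asymptote fixed at 0; per-allele mean log₁₀ EC50; alleles called
  *reduced* when their EC50 exceeds the reference allele's by more than
  10-fold (Δlog₁₀ EC50 > 1, strict).
* **Covariate analysis** — univariate and multivariate logistic regression
  of positivity on clinical covariates, reported as odds ratios with Wald
  95% CIs; explicit separation detection; a 2×2 cross-product helper with
  Haldane–Anscombe correction.
* **Synthetic cohorts** — Hardy-Weinberg genotype sampling from
  per-population allele-frequency vectors, a logistic-link staining model
  with class-conditional P-score distributions, and noisy LL3 curves, so the
  whole pipeline is testable end to end without patient-level data.

A thin CLI (`magescreen screen|screen-hla|screen-ihc|concordance|potency|covariates|simulate`)
wraps the library for shell use; `examples/` holds one narrative script per
capability.

## Worked example

Typing-assay validation with 70 reference samples, all concordant
(`examples/concordance_bounds.py`):

```text
n: 70
concordant: 70
proportion_pct: 100.0
clopper_pearson_lower_pct: 95.81
wilson_lower_pct: 96.28
alpha: 0.05
threshold_pct: 95.0
passes_threshold: True
```

Even with every sample concordant, a finite study only bounds the true
concordance from below: the exact (Clopper–Pearson) one-sided 95% bound is
95.81% and the Wilson score bound 96.28%. Both exceed the 95% acceptance
threshold, so the assay passes.

Potency classification (`examples/potency_classification.py`) fits simulated
replicate curves around known truths and prints:

```text
A*02:01: mean log10 EC50 = -7.78 (truth -7.8)
A*02:02: mean log10 EC50 = -8.12 (truth -8.1)
A*02:07: mean log10 EC50 = -6.56 (truth -6.5)
A*02:02 vs A*02:01: delta log10 EC50 = -0.34 -> comparable
A*02:07 vs A*02:01: delta log10 EC50 = +1.23 -> reduced
```

A\*02:02 is slightly *more* potent than the reference (comparable), while
A\*02:07's ~20-fold higher EC50 crosses the 10-fold threshold (reduced) —
the quantitative basis for leaving it out of the inclusion-allele set.

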