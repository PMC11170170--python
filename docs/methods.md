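# Methods

This note documents the models, rules and numerical choices behind
`magescreen`, and what the synthetic-data generator does and does not
emulate.

## HLA eligibility

Alleles are parsed per WHO nomenclature `locus*f1:f2[:f3[:f4]][suffix]`,
requiring at least two fields (protein-level resolution — the level at which
inclusion, exclusion and neutral A*02 alleles are distinguished). The
expression suffix, when present, must be one of N/L/S/C/A/Q.

P groups collect alleles with identical protein sequence over the α1/α2
peptide-binding domains; members are functionally interchangeable for
peptide presentation, so eligibility is decided on P-group identity.
The table loader reads the IMGT `hla_nom_p.txt` dialect
(`locus*;a1/a2/...;group`); both full names and two-field projections are
indexed. Lookup is total: an allele absent from the table resolves to a
singleton group named after its two-field projection. Rationale: rare
alleles do occur in screening data and are neutral unless the table says
otherwise, so an error would be the wrong failure mode. A small packaged
table covers the groups the rules distinguish (02:01P including 02:09 and
02:642, 02:02P, 02:03P, 02:05P, 02:06P, 02:07P) plus common neutral HLA-A
alleles; production use should load the full IMGT file.

A candidate pair is **eligible** iff some expressed allele lies in an
inclusion group and none lies in an exclusion group; exclusion dominates.
Null alleles (suffix N) count for neither side by default: a protein that
never reaches the surface can neither present the target peptide nor
trigger alloreactivity. This is a switch (`null_alleles_neutral`) because
the choice is a policy, not a fact of the data.

**Ambiguity.** A genotype-list call may carry several candidate genotypes.
Eligibility is decided only when all candidates agree (unanimity);
otherwise the call is *indeterminate* — mirroring a screening flow in which
discordant ambiguities go back for wet-lab resolution rather than being
adjudicated statistically. The engine never models which ambiguities the
resolution chemistry can actually resolve.

**Contribution categories.** Eligible patients are attributed to the
inclusion alleles responsible: any 02:01P allele puts the patient in
`A0201P` (even when combined with another inclusion allele); otherwise the
exact set of inclusion groups present names the category
(`A0202_exclusive`, `A0203_exclusive`, `A0206_exclusive`,
`A0203_and_0206_exclusive`); any other multi-group combination (e.g. 02:02
with 02:03) maps to `other_mixed` rather than guessing a finer label. The
categories partition the eligible count — a tested invariant. The summary
also reports the share of eligible patients outside `A0201P` (computed as
1 − A0201P/eligible, so `other_mixed` counts toward it): the statistic
showing how much the rarer inclusion alleles extend eligibility beyond an
A*02:01-only rule.

Patients carrying both an inclusion and an exclusion allele are counted
ineligible (exclusion dominance) and appear nowhere in the eligible
breakdown.

**Display rounding.** Rates are kept at full precision internally and
rounded half-up at render time only (one decimal for eligibility
percentages, two decimals for concordance bounds, nearest integer for
prevalence). Python's default banker's rounding would print 8.571% as 9%
either way but differs on exact halves; half-up matches clinical-report
convention.

## Typing concordance

A validation sample is concordant when the unambiguous reference genotype
equals the assay call or is contained among its candidates, compared as
unordered pairs at two-field resolution by default (a `full` mode compares
all typed fields plus suffix). The accuracy claim is a one-sided lower
confidence bound on the concordance proportion against a 95% threshold;
both bounds must clear it:

* **Clopper–Pearson (exact)**: the α-quantile of Beta(x, n−x+1); 0 at
  x = 0; α^(1/n) at x = n.
* **Wilson score**: the lower root of (p̂−p)² = z²p(1−p)/n with
  z = Φ⁻¹(1−α), floored at 0. z is computed from the normal quantile at
  full precision — a hard-coded 1.645 changes the second decimal of the
  70/70 bound.

Both implementations are tested against independent root-solving oracles
(the exact binomial tail equation and the score equation) to 1e-9 on a
randomized (x, n, α) grid, not against each other: neither bound dominates
the other universally, so no ordering is asserted.

## IHC scoring

The P score is the percent of tumor cells staining at ≥ 2+ intensity
(pct2 + pct3); positivity is P ≥ 30 with an inclusive boundary. The
pre-amendment rule (≥ 10% at ≥ 1+) ships as `LEGACY_CUTOFF`, not the
default. Intensities are ordinal ranks 0–3. Records validate that the four
intensity percentages are non-negative and sum to 100 ± 0.5 (pathologist
estimates are rounded).

Patients with several samples: patient-level positivity is "any positive
sample", and for the paired primary-vs-metastatic analysis each location is
represented by its maximum P score — consistent with a screening flow in
which any qualifying tissue, regardless of origin, qualifies the patient.
Prevalence defaults to counting patients, with a per-sample mode, because
denominators built from samples double-count multi-sample patients.
Archival-time strata are half-open intervals [lo, hi) so each sample falls
in exactly one bin. The per-group median P score is over all group members,
positive or not (it is an expression-level summary, not a
positives-only one).

## Potency

The dose-response model is the three-parameter log-logistic with lower
asymptote 0: y = d / (1 + exp(b(ln x − ln e))), fitted by least squares in
(b, d, log₁₀ e) with d bounded positive. With the activation-assay
convention used here, increasing curves have b < 0. Starting values:
d₀ = max response, e₀ = the tested concentration nearest half-max, b₀ = ±1,
refined over a fixed five-point grid of jittered multi-starts (both slope
signs) keeping the best residual — fixed, so fits are deterministic given
the data. Tolerances: ftol 1e-10, xtol 1e-12, max 1500 function
evaluations. Flat curves (response range ≈ 0) raise a degenerate-fit error
since no EC50 is identifiable; an EC50 landing more than 2 log units
outside the tested range is flagged extrapolated. Fits are scale- and
shift-equivariant (tested), and cross-checked against an independent lmfit
optimisation of the same model.

Per-allele potency is the arithmetic mean log₁₀ EC50 over converged
replicate fits (non-converged fits dropped with a warning). Classification
vs the reference allele: *reduced* iff Δlog₁₀ EC50 > log₁₀(fold threshold),
strict, with a 10-fold default — a delta of exactly 1.0 log unit is still
comparable. The exclusion of A*02:05 rests on alloreactivity evidence, not
potency; it enters the rule set as configuration, never as a computation.

## Covariate analysis

Odds ratios come from logistic regression fit by maximum likelihood
(statsmodels Newton iterations — the same estimates IRLS converges to),
with Wald 95% intervals exp(β̂ ± z·se) — chosen over profile intervals to
match the 2×2 closed form exactly, an equivalence the tests assert at 1e-6.
Categorical covariates are dummy-coded against a declared reference level
(first sorted level by default) so ORs are reproducible. Univariate mode
fits one term per model (crude ORs); multivariate fits all terms jointly
(adjusted). Separation — constant outcome, perfect predictor, diverging
coefficient (|β̂| > 15), or non-convergence in 100 iterations — raises an
explicit error naming the term rather than reporting meaningless intervals.
The 2×2 helper alone applies the Haldane–Anscombe +0.5 correction on single
zero cells (with a warning); two zero cells in a line leave the OR
undefined.

## Synthetic cohorts

The generator exists because screening studies publish aggregate tables,
not patient-level data; it provides cohorts with the statistical structure
the analysis assumes so every stage can be verified against known ground
truth.

* **Genotypes**: each patient draws a population from the configured mix,
  then two independent alleles from that population's frequency vector
  (Hardy-Weinberg). The default mix (79.5% White not-Hispanic, 6% Hispanic,
  6.5% Black, 8% Asian) mirrors a large North-American/European screening
  population, and the illustrative A*02 frequencies are set so carrier
  fractions 1−(1−f)² land near public registry figures (A*02:01P in ~47% of
  White, ~18% of Asian, ~23% of Black donors), with the balance on common
  neutral alleles. With probability `ambiguity_rate` (default 0.05) a call
  gains a spurious second candidate; half of those are forced
  eligibility-discordant so the indeterminate path is exercised, half are
  random draws.
* **Staining**: positivity is Bernoulli(expit(η)) with
  η = intercept[indication] + β_age·(age−60)/10 + β_hist·[SCC] +
  β_loc·[metastatic] + β_arch·archival. Default intercepts give the
  indication spread seen in screening (synovial sarcoma ~70%, gastric ~9%,
  ~26% overall); all covariate coefficients default to 0 so associations
  are opt-in ground truth. P scores are Beta draws scaled to [30, 100] for
  positives and [0, 30) for negatives, so class-conditional draws respect
  the cutoff by construction; the positive mass splits 60/40 between 2+ and
  3+ (arbitrary — the P score is invariant to the split, a tested
  property) and the remainder 70/30 between 0 and 1+. Ages are uniform
  18–75 (the screening protocol's enrollment window); archival times
  exponential, mean 1.5 years, capped at 20 (most screening samples are
  recent blocks, with a long tail).
* **Dose-response**: LL3 curves around configured truths with additive
  Gaussian noise truncated at 0.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, one child stream per product, so cohorts are reproducible and the
three products are independently perturbable.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: haplotype structure and linkage (alleles are
drawn independently, whereas real co-segregation within populations biases
multi-allele carrier rates); which ambiguities arise from real typing
chemistry; within-patient correlation of multiple tissue blocks; non-random
missingness of demographics; indication-dependent covariate distributions
(age, histology and location are drawn independently of indication); and
measurement error in the intensity percentages themselves.

## Problem sizes and determinism

The test suite runs the heavier checks at sizes chosen to make Monte-Carlo
bounds meaningful while keeping the default run fast: carrier-fraction and
end-to-end pipeline checks at n = 10,000 with 3-standard-error bands,
logistic OR recovery over 200 replicates of n = 500, Wald coverage over
1,000 simulated 2×2 tables, bound-vs-oracle agreement on randomized grids
of 40–60 points, and per-curve LL3 recovery over 100 curves. Property tests
(hypothesis) are derandomised; all simulation tests use fixed seeds, so the
suite is deterministic. `scripts/acceptance.py` recomputes the headline
quantities from scratch at the same sizes, seeding every stream from
`--seed`.

## Known limitations

* The packaged P-group table is a minimal subset; analyses of real typing
  data must load the full IMGT table.
* Eligibility summaries treat each row as one patient; duplicate typing
  records are not deduplicated.
* The logistic module fits main effects only (no interactions, model
  selection, or survival outcomes), and the regression declines separated
  data rather than applying penalised alternatives.
* Fold-change classification compares mean log₁₀ EC50s without propagating
  replicate-level uncertainty into the call.
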