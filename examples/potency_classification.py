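"""Dose-response potency of HLA-A*02 subtypes: LL3 fits and fold-change calls.

Simulates replicate cell-ELISA curves for three alleles around known
log10 EC50 truths (-7.8 for A*02:01, -8.1 for A*02:02, -6.5 for A*02:07),
fits each replicate with the three-parameter log-logistic model, averages
log10 EC50 per allele, and classifies each allele against the A*02:01
reference at a 10-fold threshold.
"""

from magescreen.potency import (
    DoseResponseCurve,
    average_log_ec50,
    classify_allele_potency,
    fit_ll3,
)
from magescreen.simulate import simulate_dose_response

TRUTHS = {"A*02:01": -7.8, "A*02:02": -8.1, "A*02:07": -6.5}
CONC = tuple(10.0**e for e in range(-11, -3))  # 1e-11 .. 1e-4 M

means = {}
for seed_offset, (allele, truth) in enumerate(sorted(TRUTHS.items())):
    df = simulate_dose_response((-1.0, 1.0, truth), CONC, noise_sd=0.05,
                                replicates=10, seed=100 + seed_offset,
                                allele=allele)
    fits = [
        fit_ll3(DoseResponseCurve(allele, tuple(sub["concentration_M"]),
                                  tuple(sub["response"]), rep))
        for rep, sub in df.groupby("replicate")
    ]
    means[allele] = average_log_ec50(fits)
    print(f"{allele}: mean log10 EC50 = {means[allele]:+.2f} (truth {truth:+.1f})")

for allele in ("A*02:02", "A*02:07"):
    call = classify_allele_potency(means[allele], means["A*02:01"], allele=allele)
    print(f"{allele} vs A*02:01: delta log10 EC50 = "
          f"{call.delta_log10_ec50:+.2f} -> {call.classification}")
# A*02:02 sits ~0.3 log units below the reference (slightly more potent):
# comparable. A*02:07 sits ~1.3 log units above (a ~20-fold higher EC50,
# beyond the 10-fold threshold): reduced -- the basis for excluding it from
# the inclusion-allele set.
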