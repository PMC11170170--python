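"""Covariate association with MAGE-A4 positivity: odds ratios with Wald CIs.

Generates a synthetic NSCLC-like cohort in which squamous histology truly
carries a 10-fold odds of positivity, then fits univariate (crude) and
multivariate (adjusted) logistic models and prints the odds-ratio table.
"""

import math

from magescreen.covariates import fit_logistic, odds_ratio_2x2, or_table
from magescreen.ihc import is_positive, records_to_frame
from magescreen.simulate import IHCModelConfig, simulate_ihc
import pandas as pd

config = IHCModelConfig(
    indication_mix={"NSCLC": 1.0},
    intercepts={"NSCLC": math.log(0.15 / 0.85)},   # ~15% positivity in AC
    histology_coef=math.log(10.0),                 # true OR 10 for SCC vs AC
    age_coef=0.0,
    seed=11,
)
cohort = pd.DataFrame({"patient_id": [f"P{i}" for i in range(2000)]})
records = simulate_ihc(config, cohort)
table = records_to_frame(records)
table["positive"] = [is_positive(r) for r in records]

crude = fit_logistic(table, ["histology", "tissue_location"], mode="univariate")
adjusted = fit_logistic(table, ["histology", "tissue_location"], mode="multivariate")
print("univariate (crude):")
print(or_table(crude).to_string(index=False))
print("multivariate (adjusted):")
print(or_table(adjusted).to_string(index=False))

ct = pd.crosstab(table["histology"], table["positive"])
closed = odds_ratio_2x2(int(ct.loc["SCC", True]), int(ct.loc["SCC", False]),
                        int(ct.loc["AC", True]), int(ct.loc["AC", False]))
print(f"2x2 cross-product check: OR = {closed.odds_ratio:.2f}")
# The histology odds ratio lands near the generating value of 10 with a 95%
# Wald CI covering it, while tissue location (no effect simulated) stays near
# 1; the single-term logistic fit and the 2x2 cross-product agree exactly.
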