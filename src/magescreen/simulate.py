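"""Synthetic screening cohorts: genotypes, IHC staining records, and
dose-response curves with the statistical structure the analysis assumes.

The generator exists so every pipeline stage can be exercised end-to-end
without patient-level data (which screening studies do not publish). It
emulates:

* diploid HLA-A genotypes drawn per population under Hardy-Weinberg
  (two independent draws from the population's allele-frequency vector),
  with a configurable rate of ambiguous calls carrying a spurious second
  candidate genotype;
* zero-inflated tumor staining whose positivity follows a logistic model in
  indication, age, histology, tissue location and archival time, with
  class-conditional P-score distributions (Beta laws scaled above / below
  the positivity cutoff);
* noisy sigmoidal LL3 dose-response curves around known true parameters.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning (one child stream per product), so cohorts are reproducible and the
three products are independently perturbable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .hla import (
    DEFAULT_RULES,
    EligibilityRuleSet,
    GenotypeCall,
    PGroupTable,
    assess_candidate,
    builtin_pgroup_table,
    parse_allele,
)
from .ihc import StainingRecord
from .potency import ll3

__all__ = [
    "CohortConfig",
    "IHCModelConfig",
    "default_cohort_config",
    "default_ihc_config",
    "simulate_genotypes",
    "simulate_ihc",
    "simulate_dose_response",
]


def _validate_simplex(name: str, probs: dict, tol: float = 1e-9) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {total!r})")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} has negative entries")


@dataclass(frozen=True)
class CohortConfig:
    """Genotype-cohort parameters.

    ``allele_freqs`` maps population -> (allele name -> frequency); each
    vector must include enough mass on non-A*02 alleles (a catch-all
    ``other`` entry is allowed and materialises as ``A*31:01``, a neutral
    allele). ``ambiguity_rate`` is the probability a call carries a second
    spurious candidate genotype.
    """

    n_patients: int
    population_mix: dict
    allele_freqs: dict
    ambiguity_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        _validate_simplex("population_mix", self.population_mix)
        for pop, freqs in self.allele_freqs.items():
            _validate_simplex(f"allele_freqs[{pop}]", freqs)
        missing = set(self.population_mix) - set(self.allele_freqs)
        if missing:
            raise ValueError(f"populations without frequency vectors: {sorted(missing)}")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")


#: Illustrative per-population HLA-A frequency vectors. The A*02 inclusion
#: allele frequencies are chosen so carrier fractions 1-(1-f)^2 land near the
#: public registry figures the screening expectations rest on (A*02:01P in
#: roughly 47% of White, 18% of Asian and 23% of Black donors); the remaining
#: mass sits on common neutral alleles.
_DEFAULT_FREQS = {
    "white_not_hispanic": {
        "A*02:01": 0.27, "A*02:05": 0.005, "A*02:06": 0.005,
        "A*01:01": 0.17, "A*03:01": 0.15, "A*24:02": 0.10, "A*11:01": 0.06,
        "A*26:01": 0.04, "A*32:01": 0.04, "A*68:01": 0.045, "A*29:02": 0.035,
        "A*23:01": 0.02, "A*30:01": 0.02, "A*31:01": 0.04,
    },
    "hispanic": {
        "A*02:01": 0.21, "A*02:06": 0.04, "A*02:05": 0.01, "A*02:02": 0.005,
        "A*24:02": 0.15, "A*01:01": 0.08, "A*03:01": 0.08, "A*68:01": 0.07,
        "A*11:01": 0.04, "A*30:01": 0.03, "A*31:01": 0.285,
    },
    "black": {
        "A*02:01": 0.12, "A*02:02": 0.04, "A*02:05": 0.015, "A*02:06": 0.005,
        "A*01:01": 0.06, "A*03:01": 0.08, "A*23:01": 0.11, "A*30:01": 0.10,
        "A*68:01": 0.06, "A*33:03": 0.05, "A*24:02": 0.04, "A*31:01": 0.32,
    },
    "asian": {
        "A*02:01": 0.095, "A*02:03": 0.06, "A*02:06": 0.05, "A*02:07": 0.06,
        "A*11:01": 0.17, "A*24:02": 0.17, "A*33:03": 0.08, "A*02:05": 0.002,
        "A*01:01": 0.04, "A*03:01": 0.04, "A*31:01": 0.233,
    },
}


def default_cohort_config(n_patients: int = 1000, seed: int = 0) -> CohortConfig:
    """A screening-study-like cohort: mostly White-not-Hispanic patients with
    Hispanic, Black and Asian minorities, illustrative frequency vectors."""
    return CohortConfig(
        n_patients=n_patients,
        population_mix={
            "white_not_hispanic": 0.795,
            "hispanic": 0.06,
            "black": 0.065,
            "asian": 0.08,
        },
        allele_freqs={k: dict(v) for k, v in _DEFAULT_FREQS.items()},
        ambiguity_rate=0.05,
        seed=seed,
    )


_RACE_LABEL = {
    "white_not_hispanic": ("White", "Not Hispanic or Latino"),
    "hispanic": ("White", "Hispanic or Latino"),
    "black": ("Black or African American", "Not Hispanic or Latino"),
    "asian": ("Asian", "Not Hispanic or Latino"),
}

# spurious-candidate building blocks: one clearly eligible pair and one
# clearly neutral pair, used to force eligibility-discordant ambiguity
_ELIGIBLE_PAIR = "A*02:01+A*68:01"
_NEUTRAL_PAIR = "A*03:01+A*24:02"


def simulate_genotypes(
    config: CohortConfig,
    rules: EligibilityRuleSet = DEFAULT_RULES,
    table: Optional[PGroupTable] = None,
) -> pd.DataFrame:
    """Draw a genotyped cohort (``hla_typing.csv`` schema).

    Each patient draws a population from the mix and two independent alleles
    from that population's frequency vector (Hardy-Weinberg). With
    probability ``ambiguity_rate`` the call gains a spurious second
    candidate; half of those spurious candidates are built to disagree with
    the true pair on eligibility (exercising the indeterminate path), half
    are random draws.
    """
    table = table if table is not None else builtin_pgroup_table()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    pops = list(config.population_mix)
    pop_probs = np.array([config.population_mix[p] for p in pops], dtype=float)
    pop_idx = rng.choice(len(pops), size=config.n_patients, p=pop_probs / pop_probs.sum())

    rows = []
    for i in range(config.n_patients):
        pop = pops[pop_idx[i]]
        freqs = config.allele_freqs[pop]
        names = list(freqs)
        probs = np.array([freqs[a] for a in names], dtype=float)
        probs = probs / probs.sum()
        a1, a2 = (names[j] for j in rng.choice(len(names), size=2, p=probs))
        a1 = "A*31:01" if a1 == "other" else a1
        a2 = "A*31:01" if a2 == "other" else a2
        genotype = f"{a1}+{a2}"
        if rng.random() < config.ambiguity_rate:
            if rng.random() < 0.5:
                true_status = assess_candidate(
                    (parse_allele(a1), parse_allele(a2)), rules, table
                )
                spurious = _NEUTRAL_PAIR if true_status == "eligible" else _ELIGIBLE_PAIR
            else:
                s1, s2 = (names[j] for j in rng.choice(len(names), size=2, p=probs))
                spurious = f"{s1}+{s2}"
            genotype = f"{genotype}|{spurious}"
        race, ethnicity = _RACE_LABEL.get(pop, (pop, "Not recorded"))
        rows.append(
            {
                "patient_id": f"P{i:06d}",
                "genotype": genotype,
                "race": race,
                "ethnicity": ethnicity,
                "population": pop,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IHCModelConfig:
    """Staining-cohort parameters (logistic positivity model).

    The linear predictor is
    ``intercept[indication] + age_coef*(age-60)/10 + histology_coef*[SCC]
    + metastatic_coef*[metastatic] + archival_coef*archival_years``;
    positivity is Bernoulli(expit(.)). P scores are drawn from Beta laws
    scaled to [cutoff, 100] for positives and [0, cutoff) for negatives, so
    class-conditional draws respect the cutoff by construction; the positive
    mass is split 60/40 between the 2+ and 3+ intensity grades (the P score
    is invariant to this split) and the remainder between 0 and 1+.
    """

    indication_mix: dict
    intercepts: dict  # indication -> logit-scale intercept
    age_coef: float = 0.0
    histology_coef: float = 0.0
    metastatic_coef: float = 0.0
    archival_coef: float = 0.0
    positive_beta: tuple[float, float] = (2.0, 2.0)
    negative_beta: tuple[float, float] = (1.0, 4.0)
    cutoff_pscore: float = 30.0
    metastatic_fraction: float = 0.3
    scc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_simplex("indication_mix", self.indication_mix)
        missing = set(self.indication_mix) - set(self.intercepts)
        if missing:
            raise ValueError(f"indications without intercepts: {sorted(missing)}")
        for name, (a, b) in (("positive_beta", self.positive_beta),
                             ("negative_beta", self.negative_beta)):
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} parameters must be positive")
        if not 0 < self.cutoff_pscore < 100:
            raise ValueError("cutoff_pscore must be inside (0, 100)")


def default_ihc_config(seed: int = 0) -> IHCModelConfig:
    """Indication mix and intercepts shaped like the screening prevalence
    spread (synovial sarcoma high, gastric low, ~26% overall)."""
    mix = {
        "SyS": 0.115, "MRCLS": 0.038, "NSCLC": 0.261, "melanoma": 0.139,
        "ovarian": 0.129, "urothelial": 0.053, "head_and_neck": 0.114,
        "esophageal": 0.057, "EGJ": 0.053, "gastric": 0.041,
    }
    logit = lambda p: math.log(p / (1 - p))
    intercepts = {
        "SyS": logit(0.70), "MRCLS": logit(0.40), "NSCLC": logit(0.14),
        "melanoma": logit(0.16), "ovarian": logit(0.24), "urothelial": logit(0.32),
        "head_and_neck": logit(0.22), "esophageal": logit(0.21),
        "EGJ": logit(0.26), "gastric": logit(0.09),
    }
    return IHCModelConfig(indication_mix=mix, intercepts=intercepts, seed=seed)


def simulate_ihc(config: IHCModelConfig, cohort: pd.DataFrame) -> list[StainingRecord]:
    """Draw one staining record per cohort patient (``ihc.csv`` schema).

    ``cohort`` is a frame with at least ``patient_id`` (the genotype frame
    from :func:`simulate_genotypes` works). Ages are uniform 18-75 years at
    biopsy, archival times exponential with mean 1.5 years (capped at 20),
    histology AC/SCC per ``scc_fraction``, location per
    ``metastatic_fraction``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    indications = list(config.indication_mix)
    probs = np.array([config.indication_mix[i] for i in indications], dtype=float)
    ind_idx = rng.choice(len(indications), size=n, p=probs / probs.sum())
    ages = rng.uniform(18.0, 75.0, size=n)
    archival = np.minimum(rng.exponential(1.5, size=n), 20.0)
    scc = rng.random(n) < config.scc_fraction
    metastatic = rng.random(n) < config.metastatic_fraction

    eta = (
        np.array([config.intercepts[indications[k]] for k in ind_idx])
        + config.age_coef * (ages - 60.0) / 10.0
        + config.histology_coef * scc
        + config.metastatic_coef * metastatic
        + config.archival_coef * archival
    )
    positive = rng.random(n) < expit(eta)

    a_pos, b_pos = config.positive_beta
    a_neg, b_neg = config.negative_beta
    cut = config.cutoff_pscore
    draws = np.where(
        positive,
        cut + (100.0 - cut) * rng.beta(a_pos, b_pos, size=n),
        np.nextafter(cut, 0.0) * rng.beta(a_neg, b_neg, size=n),
    )

    records = []
    for k in range(n):
        score = float(draws[k])
        pct2, pct3 = 0.6 * score, 0.4 * score
        rest = 100.0 - score
        pct1 = 0.3 * rest
        pct0 = rest - pct1
        records.append(
            StainingRecord(
                sample_id=f"S{k:06d}",
                patient_id=str(cohort["patient_id"].iloc[k]),
                tumor_type=indications[ind_idx[k]],
                histology="SCC" if scc[k] else "AC",
                tissue_location="metastatic" if metastatic[k] else "primary",
                patient_age=float(ages[k]),
                archival_years=float(archival[k]),
                pct_intensity=(pct0, pct1, pct2, pct3),
            )
        )
    return records


def simulate_dose_response(
    truth: tuple[float, float, float],
    concentrations: Sequence[float],
    noise_sd: float = 0.05,
    replicates: int = 1,
    seed: int = 0,
    allele: str = "allele",
) -> pd.DataFrame:
    """Replicate LL3 curves around ``truth`` = (b, d, log10_ec50) with
    additive Gaussian noise truncated at zero (``doseresponse.csv`` schema).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    b, d, log10_e = truth
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    clean = ll3(conc, b, d, log10_e)
    rows = []
    for rep in range(1, replicates + 1):
        noisy = np.maximum(0.0, clean + rng.normal(0.0, noise_sd, size=conc.size))
        for x, y in zip(conc, noisy):
            rows.append(
                {"allele": allele, "replicate": str(rep),
                 "concentration_M": float(x), "response": float(y)}
            )
    return pd.DataFrame(rows)
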