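"""Typing-assay concordance against reference genotypes, with exact one-sided
lower confidence bounds.

Assay validation for an HLA typing method compares the assay genotype with a
reference genotype for each sample. A sample is concordant when the reference
genotype is either identical to the assay call (no ambiguity) or included
among the assay's candidate genotypes (ambiguous call). The accuracy claim is
then a one-sided lower confidence bound on the concordance proportion,
compared with a 95% acceptance threshold; both the Clopper-Pearson exact
bound and the Wilson score bound are computed (with 70/70 concordant samples
and alpha = 0.05 these are 95.81% and 96.28%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from ._util import round_half_up
from .hla import GenotypeCall, HLAAllele

__all__ = [
    "ConcordanceRecord",
    "ConcordanceSummary",
    "is_concordant",
    "clopper_pearson_lower",
    "wilson_lower",
    "summarize_concordance",
]


@dataclass(frozen=True)
class ConcordanceRecord:
    """One validation sample: unambiguous reference vs (possibly ambiguous) assay call."""

    sample_id: str
    reference: GenotypeCall
    assay: GenotypeCall

    def __post_init__(self) -> None:
        if self.reference.ambiguous:
            raise ValueError(
                f"sample {self.sample_id}: reference genotype must be unambiguous"
            )


def _pair_key(pair: Sequence[HLAAllele], resolution: str) -> frozenset:
    if resolution == "two_field":
        names = [a.two_field_name for a in pair]
    elif resolution == "full":
        names = [a.format() for a in pair]
    else:
        raise ValueError(f"unknown resolution {resolution!r}")
    # unordered pair; a Counter-like frozenset of (name, count) handles homozygotes
    if names[0] == names[1]:
        return frozenset({(names[0], 2)})
    return frozenset({(names[0], 1), (names[1], 1)})


def is_concordant(record: ConcordanceRecord, resolution: str = "two_field") -> bool:
    """True iff the reference pair matches any assay candidate (unordered).

    ``resolution`` selects the comparison level: ``"two_field"`` (protein
    level, the level at which eligibility is decided; default) or ``"full"``
    (all typed fields plus suffix).
    """
    ref_key = _pair_key(record.reference.candidates[0], resolution)
    return any(_pair_key(pair, resolution) == ref_key for pair in record.assay.candidates)


def _check_xn_alpha(x: int, n: int, alpha: float) -> None:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


def clopper_pearson_lower(x: int, n: int, alpha: float = 0.05) -> float:
    """Exact (Clopper-Pearson) one-sided lower confidence bound for a
    binomial proportion with ``x`` successes in ``n`` trials.

    The bound is the alpha-quantile of Beta(x, n - x + 1); for x = n this
    reduces to the closed form alpha**(1/n), and for x = 0 it is 0.
    """
    _check_xn_alpha(x, n, alpha)
    if x == 0:
        return 0.0
    if x == n:
        return float(alpha ** (1.0 / n))
    return float(stats.beta.ppf(alpha, x, n - x + 1))


def wilson_lower(x: int, n: int, alpha: float = 0.05) -> float:
    """One-sided Wilson score lower confidence bound.

    Inverts the normal-approximation score test with
    z = Phi^-1(1 - alpha):

        (p̂ + z²/2n − z·sqrt(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)

    floored at 0. z comes from the normal quantile at full precision, not a
    rounded table value.
    """
    _check_xn_alpha(x, n, alpha)
    z = float(stats.norm.ppf(1.0 - alpha))
    phat = x / n
    denom = 1.0 + z * z / n
    center = phat + z * z / (2.0 * n)
    half = z * math.sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n))
    return max(0.0, (center - half) / denom)


@dataclass(frozen=True)
class ConcordanceSummary:
    n: int
    concordant: int
    proportion: float
    cp_lower: float
    wilson_lower: float
    alpha: float
    threshold: float
    passes_threshold: bool

    def display(self) -> dict:
        """Report-style view with percentages rounded half-up to two decimals."""
        return {
            "n": self.n,
            "concordant": self.concordant,
            "proportion_pct": round_half_up(100.0 * self.proportion, 2),
            "clopper_pearson_lower_pct": round_half_up(100.0 * self.cp_lower, 2),
            "wilson_lower_pct": round_half_up(100.0 * self.wilson_lower, 2),
            "alpha": self.alpha,
            "threshold_pct": 100.0 * self.threshold,
            "passes_threshold": self.passes_threshold,
        }


def summarize_concordance(
    records: Sequence[ConcordanceRecord],
    alpha: float = 0.05,
    threshold: float = 0.95,
    resolution: str = "two_field",
) -> ConcordanceSummary:
    """Count concordant records and evaluate both lower bounds against the
    acceptance threshold (pass requires *both* bounds to exceed it)."""
    if not records:
        raise ValueError("no concordance records")
    n = len(records)
    x = sum(is_concordant(r, resolution) for r in records)
    cp = clopper_pearson_lower(x, n, alpha)
    wl = wilson_lower(x, n, alpha)
    return ConcordanceSummary(
        n=n,
        concordant=x,
        proportion=x / n,
        cp_lower=cp,
        wilson_lower=wl,
        alpha=alpha,
        threshold=threshold,
        passes_threshold=bool(cp > threshold and wl > threshold),
    )
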