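"""Three-parameter log-logistic (LL3) dose-response fitting and potency
classification of HLA subtypes.

The in vitro potency of the TCR T cell product against a peptide presented
by each HLA-A*02 subtype is summarised by the EC50 of a cell-ELISA response
curve. Curves are fit with the three-parameter log-logistic model with the
lower asymptote fixed at zero,

    y(x) = d / (1 + exp(b * (ln x - ln e))),

where ``d`` is the upper asymptote (response units), ``e`` the EC50 (molar)
and ``b`` the Hill slope (negative ``b`` gives a response increasing with
concentration, the convention used for activation readouts). Per-allele
potency is the mean log10 EC50 across replicate fits; an allele is called
``reduced`` relative to the reference when its EC50 exceeds the reference's
by more than a fold threshold (default 10-fold, i.e. delta log10 EC50 > 1,
strict).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "FitResult",
    "PotencyCall",
    "DegenerateFitError",
    "ll3",
    "fit_ll3",
    "average_log_ec50",
    "classify_allele_potency",
]

LN10 = math.log(10.0)


class DegenerateFitError(ValueError):
    """Raised when the data carry no dose-response signal (flat curve)."""


@dataclass(frozen=True)
class DoseResponseCurve:
    """One replicate curve: response vs molar peptide concentration."""

    allele: str
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    replicate: str = "1"

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses differ in length")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive (molar)")
        if any(r < 0 for r in self.responses):
            raise ValueError("responses must be non-negative")
        if len(set(self.concentrations)) < 4:
            raise ValueError("need >= 4 distinct concentrations to fit 3 parameters")


@dataclass(frozen=True)
class FitResult:
    allele: str
    slope: float          # b
    upper: float          # d, response units
    log10_ec50: float
    residual_ss: float
    converged: bool
    extrapolated: bool = False  # EC50 > 2 log units outside the tested range
    replicate: str = "1"


def ll3(x, b: float, d: float, log10_e: float):
    """LL3 model value(s): d / (1 + exp(b (ln x − ln e)))."""
    x = np.asarray(x, dtype=float)
    z = b * (np.log(x) - LN10 * log10_e)
    # clip to keep exp finite; 700 is near the float64 overflow edge
    return d / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))


# multi-start jitter: slope sign flips and EC50/d perturbations, fixed so the
# fit is deterministic given the data
_STARTS = (
    (1.0, 1.0, 0.0),
    (-1.0, 1.0, 0.0),
    (1.0, 1.2, 0.5),
    (-1.0, 1.2, 0.5),
    (-2.0, 0.9, -0.5),
)


def fit_ll3(curve: DoseResponseCurve, init: Optional[tuple[float, float, float]] = None) -> FitResult:
    """Least-squares LL3 fit of one curve.

    Starting values default to d0 = max response, e0 = the tested
    concentration nearest half-max, b0 = +/-1, refined over a small fixed
    grid of jittered multi-starts; the best residual wins. Raises
    :class:`DegenerateFitError` on flat data (no EC50 identifiable); a fit
    that never converges is returned with ``converged=False``.
    """
    x = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    span = float(y.max() - y.min())
    if span <= 1e-12 * max(1.0, abs(float(y.max()))):
        raise DegenerateFitError(
            f"allele {curve.allele}: constant response, no EC50 identifiable"
        )

    d0 = float(y.max())
    half = 0.5 * d0
    e0_log10 = float(np.log10(x[np.argmin(np.abs(y - half))]))

    def residuals(theta):
        b, d, le = theta
        return ll3(x, b, d, le) - y

    best = None
    if init is not None:
        start_list = [tuple(init)]
    else:
        start_list = [(sb, d0 * sd, e0_log10 + se) for sb, sd, se in _STARTS]
    for b_s, d_s, e_s in start_list:
        try:
            sol = least_squares(
                residuals,
                x0=np.array([b_s, d_s, e_s]),
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                ftol=1e-10,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=500 * 3,
            )
        except ValueError:
            continue
        ss = float(np.sum(sol.fun**2))
        if best is None or ss < best[1]:
            best = (sol, ss)
    if best is None:
        return FitResult(curve.allele, math.nan, math.nan, math.nan, math.inf,
                         converged=False, replicate=curve.replicate)
    sol, ss = best
    b, d, le = (float(v) for v in sol.x)
    lo, hi = math.log10(float(x.min())), math.log10(float(x.max()))
    extrapolated = not (lo - 2.0 <= le <= hi + 2.0)
    return FitResult(
        allele=curve.allele,
        slope=b,
        upper=d,
        log10_ec50=le,
        residual_ss=ss,
        converged=bool(sol.success),
        extrapolated=extrapolated,
        replicate=curve.replicate,
    )


def average_log_ec50(fits: Sequence[FitResult]) -> float:
    """Arithmetic mean log10 EC50 over converged replicate fits.

    Non-converged fits are dropped with a warning; all-non-converged input
    is an error.
    """
    if not fits:
        raise ValueError("no fits")
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to average")
    if len(converged) < len(fits):
        warnings.warn(
            f"averaging over {len(converged)}/{len(fits)} converged fits",
            stacklevel=2,
        )
    return float(np.mean([f.log10_ec50 for f in converged]))


@dataclass(frozen=True)
class PotencyCall:
    allele: str
    delta_log10_ec50: float  # vs reference; positive = less potent
    classification: str      # comparable | reduced
    fold_threshold: float = 10.0


def classify_allele_potency(
    allele_mean: float,
    reference_mean: float,
    fold_threshold: float = 10.0,
    allele: str = "",
) -> PotencyCall:
    """Classify an allele's potency relative to the reference allele.

    ``reduced`` iff the allele's mean log10 EC50 exceeds the reference's by
    strictly more than log10(fold_threshold); a delta of exactly the
    threshold is still ``comparable``.
    """
    if not (math.isfinite(allele_mean) and math.isfinite(reference_mean)):
        raise ValueError("both mean log10 EC50 values must be finite")
    delta = allele_mean - reference_mean
    classification = "reduced" if delta > math.log10(fold_threshold) else "comparable"
    return PotencyCall(
        allele=allele,
        delta_log10_ec50=delta,
        classification=classification,
        fold_threshold=fold_threshold,
    )
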