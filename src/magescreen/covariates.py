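"""Association of MAGE-A4 positivity with clinical covariates: odds ratios
with Wald 95% confidence intervals from logistic regression.

Covariates (age category, sex, tumor subtype, histology, cancer-cell count
category, archival-time category, inflammatory-cell percentage) are assessed
univariately (one term per model) and multivariately (all terms jointly,
i.e. adjusted). Point estimates are exponentiated maximum-likelihood
coefficients; intervals are Wald on the log-odds scale, matching the 2x2
closed form exactly for a single binary covariate. The regression refuses to
fit separated data rather than silently shrinking; the 2x2 helper applies
the Haldane-Anscombe +0.5 correction on single zero cells, with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["ORResult", "SeparationError", "odds_ratio_2x2", "fit_logistic", "or_table"]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass(frozen=True)
class ORResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if min(self.odds_ratio, self.ci_low) <= 0:
            raise ValueError("odds ratio and CI bounds must be positive")


def odds_ratio_2x2(
    a: int, b: int, c: int, d: int, alpha: float = 0.05, term: str = "2x2"
) -> ORResult:
    """Odds ratio for the 2x2 table [[a, b], [c, d]] (exposed-positive a,
    exposed-negative b, unexposed-positive c, unexposed-negative d).

    OR = ad/bc with a Wald CI on the log scale,
    se = sqrt(1/a + 1/b + 1/c + 1/d). A single zero cell triggers the
    Haldane-Anscombe +0.5 correction (warned); two zero cells in the same
    row or column leave the OR undefined and raise.
    """
    cells = [a, b, c, d]
    if any(v < 0 or int(v) != v for v in cells):
        raise ValueError("cell counts must be non-negative integers")
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("a zero row or column leaves the odds ratio undefined")
    if 0 in cells:
        warnings.warn(
            "zero cell: applying Haldane-Anscombe +0.5 correction", stacklevel=2
        )
        a, b, c, d = (v + 0.5 for v in cells)
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(1 - alpha / 2))
    p = 2 * float(stats.norm.sf(abs(log_or) / se))
    return ORResult(
        term=term,
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=p,
        n=int(sum(cells)),
    )


def _design(
    df: pd.DataFrame,
    terms: Sequence[str],
    reference_levels: Optional[dict] = None,
) -> pd.DataFrame:
    """Dummy-coded design matrix. Categorical (object/category/bool) terms are
    expanded against a reference level (the declared one, else the first
    level in sorted order); numeric terms enter linearly."""
    reference_levels = reference_levels or {}
    cols = {}
    for term in terms:
        s = df[term]
        if s.isna().any():
            raise ValueError(f"term {term!r} has missing values")
        if s.dtype.kind in "biufc" and s.dtype != bool:
            cols[term] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            ref = str(reference_levels.get(term, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {term!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{term}[{lev} vs {ref}]"] = (s.astype(str) == lev).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "const", 1.0)
    return X


def _check_separation(X: pd.DataFrame, y: np.ndarray, params: np.ndarray) -> None:
    # a diverging coefficient (|beta| on the log-odds scale beyond ~e^15)
    # is the practical signature of quasi-separation after Newton iterations
    big = np.abs(params) > 15
    if big.any():
        culprit = X.columns[int(np.argmax(np.abs(params)))]
        raise SeparationError(f"separation detected on term {culprit!r}")


def _fit_one(df: pd.DataFrame, outcome: str, terms: Sequence[str],
             reference_levels: Optional[dict], alpha: float) -> list[ORResult]:
    y = df[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise SeparationError("outcome is constant; no model can be fit")
    X = _design(df, terms, reference_levels)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge in 100 iterations")
    _check_separation(X, y, res.params.to_numpy())
    z = float(stats.norm.ppf(1 - alpha / 2))
    out = []
    for name in X.columns:
        if name == "const":
            continue
        beta = float(res.params[name])
        se = float(res.bse[name])
        out.append(
            ORResult(
                term=name,
                odds_ratio=math.exp(beta),
                ci_low=math.exp(beta - z * se),
                ci_high=math.exp(beta + z * se),
                p_value=float(res.pvalues[name]),
                n=len(df),
            )
        )
    return out


def fit_logistic(
    table: pd.DataFrame,
    terms: Sequence[str],
    outcome: str = "positive",
    mode: str = "multivariate",
    reference_levels: Optional[dict] = None,
    alpha: float = 0.05,
) -> list[ORResult]:
    """Logistic-regression odds ratios for ``terms`` against a boolean
    ``outcome`` column.

    ``mode="univariate"`` fits each term in its own model (crude ORs);
    ``mode="multivariate"`` fits all terms jointly (adjusted ORs). Raises
    :class:`SeparationError` on complete/quasi-complete separation or
    non-convergence instead of reporting meaningless intervals.
    """
    if table.empty:
        raise ValueError("empty covariate table")
    if table[outcome].isna().any():
        raise ValueError("outcome has missing values")
    n_params = len(terms) + 1
    if len(table) <= n_params:
        raise ValueError("need more observations than parameters")
    if mode == "multivariate":
        return _fit_one(table, outcome, terms, reference_levels, alpha)
    if mode == "univariate":
        out: list[ORResult] = []
        for term in terms:
            out.extend(_fit_one(table, outcome, [term], reference_levels, alpha))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def or_table(results: Sequence[ORResult]) -> pd.DataFrame:
    """Tidy frame of OR results (term, OR, CI bounds, p, n)."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in results
        ]
    )
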