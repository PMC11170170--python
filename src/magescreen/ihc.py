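"""MAGE-A4 immunohistochemistry scoring: P scores, positivity calls, and
prevalence / agreement summaries.

Each tumor sample carries the percentage of tumor cells staining at each
intensity grade (0, 1+, 2+, 3+). The P score is the percentage of tumor
cells at >= 2+ intensity (pct2 + pct3); a sample is MAGE-A4 positive when
the P score reaches the positivity cutoff (>= 30% at >= 2+, the cutoff used
in the clinical trials; the earlier >= 1+ at 10% rule ships as the
``LEGACY_CUTOFF`` preset).

Patients may contribute several samples. Patient-level positivity is "any
positive sample"; for the paired primary-vs-metastatic agreement analysis
each tissue location is represented by its maximum P score. Display rounding
for prevalence is nearest-integer percent, half-up (6/70 prints as 9%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import rate_pct, round_half_up

__all__ = [
    "StainingRecord",
    "PositivityCutoff",
    "DEFAULT_CUTOFF",
    "LEGACY_CUTOFF",
    "p_score",
    "is_positive",
    "prevalence_by",
    "pairwise_location_agreement",
    "archival_strata",
    "reader_concordance",
    "records_to_frame",
    "frame_to_records",
]

TUMOR_TYPES = (
    "SyS", "MRCLS", "NSCLC", "melanoma", "ovarian", "urothelial",
    "head_and_neck", "esophageal", "EGJ", "gastric", "other",
)

_PCT_SUM_TOL = 0.5


@dataclass(frozen=True)
class StainingRecord:
    """One stained tumor sample with its intensity distribution and covariates.

    ``pct_intensity`` holds the percent of tumor cells at intensities
    (0, 1+, 2+, 3+); the four values must be non-negative and sum to 100
    within +/- 0.5 (pathologist estimates are rounded).
    """

    sample_id: str
    patient_id: str
    tumor_type: str
    pct_intensity: tuple[float, float, float, float]
    histology: str = "NA"          # AC | SCC | other | NA
    tissue_location: str = "NA"    # primary | metastatic | NA
    patient_age: Optional[float] = None
    archival_years: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.pct_intensity) != 4:
            raise ValueError("pct_intensity needs exactly 4 values (0, 1+, 2+, 3+)")
        if any(p < 0 for p in self.pct_intensity):
            raise ValueError(f"negative staining percentage in {self.pct_intensity}")
        total = sum(self.pct_intensity)
        if abs(total - 100.0) > _PCT_SUM_TOL:
            raise ValueError(
                f"sample {self.sample_id}: intensity percentages sum to {total}, not 100 +/- {_PCT_SUM_TOL}"
            )
        if self.archival_years is not None and self.archival_years < 0:
            raise ValueError(f"sample {self.sample_id}: negative archival time")


@dataclass(frozen=True)
class PositivityCutoff:
    """Positivity rule: P score (percent at >= ``min_intensity``) >= ``min_pscore``."""

    min_pscore: float = 30.0
    min_intensity: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.min_pscore <= 100:
            raise ValueError("min_pscore must be in [0, 100]")
        if self.min_intensity not in (0, 1, 2, 3):
            raise ValueError("min_intensity must be an intensity rank 0-3")


DEFAULT_CUTOFF = PositivityCutoff(30.0, 2)
#: Pre-amendment screening rule: >= 10% of tumor cells at >= 1+.
LEGACY_CUTOFF = PositivityCutoff(10.0, 1)


def p_score(record: StainingRecord, min_intensity: int = 2) -> float:
    """Percent of tumor cells staining at or above ``min_intensity`` (default
    2+, the protein-score definition)."""
    return float(sum(record.pct_intensity[min_intensity:]))


def is_positive(record: StainingRecord, cutoff: PositivityCutoff = DEFAULT_CUTOFF) -> bool:
    """Positivity call; the cutoff boundary is inclusive (P score 30 at the
    default rule is positive)."""
    return p_score(record, cutoff.min_intensity) >= cutoff.min_pscore


def records_to_frame(records: Iterable[StainingRecord]) -> pd.DataFrame:
    """Flatten records to the ``ihc.csv`` schema (pct0..pct3 columns)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "tumor_type": r.tumor_type,
                "histology": r.histology,
                "tissue_location": r.tissue_location,
                "patient_age": r.patient_age,
                "archival_years": r.archival_years,
                "pct0": r.pct_intensity[0],
                "pct1": r.pct_intensity[1],
                "pct2": r.pct_intensity[2],
                "pct3": r.pct_intensity[3],
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[StainingRecord]:
    """Validate and lift an ``ihc.csv``-shaped frame into records."""
    records = []
    for _, row in df.iterrows():
        records.append(
            StainingRecord(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                tumor_type=str(row["tumor_type"]),
                histology=str(row.get("histology", "NA")),
                tissue_location=str(row.get("tissue_location", "NA")),
                patient_age=None if pd.isna(row.get("patient_age")) else float(row["patient_age"]),
                archival_years=None
                if pd.isna(row.get("archival_years"))
                else float(row["archival_years"]),
                pct_intensity=(
                    float(row["pct0"]),
                    float(row["pct1"]),
                    float(row["pct2"]),
                    float(row["pct3"]),
                ),
            )
        )
    return records


def _patient_table(
    records: Sequence[StainingRecord], cutoff: PositivityCutoff
) -> pd.DataFrame:
    """Per-sample table with P scores and calls."""
    df = records_to_frame(records)
    df["p_score"] = [p_score(r, cutoff.min_intensity) for r in records]
    df["positive"] = [is_positive(r, cutoff) for r in records]
    return df


def prevalence_by(
    records: Sequence[StainingRecord],
    key: Optional[str] = None,
    cutoff: PositivityCutoff = DEFAULT_CUTOFF,
    unit: str = "patient",
) -> pd.DataFrame:
    """Positivity prevalence per group of ``key`` (a StainingRecord column
    such as ``tumor_type`` or ``histology``), plus an ``Overall`` row.

    ``unit="patient"`` (default) counts patients — a patient is positive if
    any sample is, and their P score is the per-patient maximum — matching a
    screening flow where any qualifying tissue makes the patient eligible.
    ``unit="sample"`` counts samples directly. Rates are reported at full
    precision and display-rounded to integer percent (half-up); the median P
    score is over all members of the group, positive or not.
    """
    if not records:
        raise ValueError("no staining records")
    if unit not in ("patient", "sample"):
        raise ValueError(f"unknown unit {unit!r}")
    df = _patient_table(records, cutoff)
    group_col = key if key is not None else None
    if unit == "patient":
        agg = {"positive": "max", "p_score": "max"}
        if group_col:
            agg[group_col] = "first"  # group label from the first sample
        df = df.groupby("patient_id", as_index=False).agg(agg)

    def _row(sub: pd.DataFrame, label) -> dict:
        n = len(sub)
        pos = int(sub["positive"].sum())
        return {
            "group": label,
            "n": n,
            "positive": pos,
            "rate_pct": rate_pct(pos, n),
            "rate_pct_display": round_half_up(rate_pct(pos, n), 0),
            "median_p_score": float(sub["p_score"].median()),
        }

    rows = []
    if group_col:
        for label, sub in df.groupby(group_col, sort=False):
            rows.append(_row(sub, label))
    rows.append(_row(df, "Overall"))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LocationAgreement:
    n_dual: int          # patients with both a primary and a metastatic sample
    n_agree: int         # ... whose positivity calls match across locations
    fraction: float
    n_excluded: int      # patients lacking one of the two locations

    @property
    def pct_display(self) -> float:
        return round_half_up(100.0 * self.fraction, 0)


def pairwise_location_agreement(
    records: Sequence[StainingRecord],
    cutoff: PositivityCutoff = DEFAULT_CUTOFF,
) -> LocationAgreement:
    """Agreement of the positivity call between primary and metastatic tissue
    within patients sampled at both locations (per-location maximum P score
    when a location has several samples)."""
    df = _patient_table(records, cutoff)
    df = df[df["tissue_location"].isin(["primary", "metastatic"])]
    per_loc = df.groupby(["patient_id", "tissue_location"])["p_score"].max().unstack()
    all_patients = df["patient_id"].nunique()
    dual = per_loc.dropna(subset=["primary", "metastatic"]) if {
        "primary",
        "metastatic",
    } <= set(per_loc.columns) else per_loc.iloc[0:0]
    n_dual = len(dual)
    if n_dual == 0:
        return LocationAgreement(0, 0, float("nan"), all_patients)
    # the location maxima re-enter the same cutoff rule used for samples
    agree = (
        (dual["primary"] >= cutoff.min_pscore) == (dual["metastatic"] >= cutoff.min_pscore)
    ).sum()
    return LocationAgreement(
        n_dual=n_dual,
        n_agree=int(agree),
        fraction=float(agree) / n_dual,
        n_excluded=all_patients - n_dual,
    )


def archival_strata(
    records: Sequence[StainingRecord],
    breaks: Sequence[float],
    cutoff: PositivityCutoff = DEFAULT_CUTOFF,
    unit: str = "sample",
) -> pd.DataFrame:
    """Prevalence per archival-time stratum.

    ``breaks`` are strictly increasing interior boundaries; strata are the
    half-open intervals [0, b1), [b1, b2), ..., [b_last, inf). A record at
    exactly a boundary falls in the upper stratum. Defaults to per-sample
    counting because archival time is a sample property.
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    for r in records:
        if r.archival_years is None:
            raise ValueError(f"sample {r.sample_id}: archival time missing")
    edges = [0.0, *breaks, float("inf")]
    labels = [
        f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f"[{lo:g}, inf)"
        for lo, hi in zip(edges, edges[1:])
    ]
    frames = []
    for lo, hi, label in zip(edges, edges[1:], labels):
        members = [r for r in records if lo <= r.archival_years < hi]
        if not members:
            frames.append(
                pd.DataFrame(
                    [{"group": label, "n": 0, "positive": 0, "rate_pct": float("nan"),
                      "rate_pct_display": float("nan"), "median_p_score": float("nan")}]
                )
            )
            continue
        row = prevalence_by(members, key=None, cutoff=cutoff, unit=unit).iloc[[-1]].copy()
        row["group"] = label
        frames.append(row)
    out = pd.concat(frames, ignore_index=True)
    out.insert(1, "stratum_lo", edges[:-1])
    out.insert(2, "stratum_hi", edges[1:])
    return out


def reader_concordance(
    calls_by_reader: Union[pd.DataFrame, dict],
    acceptance_floor: float = 80.0,
) -> pd.DataFrame:
    """Pairwise percent agreement of positivity calls between readers or runs.

    ``calls_by_reader`` maps reader -> {sample -> bool} (or an equivalent
    DataFrame, samples as rows, readers as columns). All readers must have
    scored the same samples. Pairs below ``acceptance_floor`` percent are
    flagged; an ``overall`` row averages the pairwise agreements.
    """
    df = pd.DataFrame(calls_by_reader)
    if df.empty or df.shape[1] < 2:
        raise ValueError("need at least two readers over a shared sample set")
    if df.isna().any().any():
        raise ValueError("mismatched sample sets between readers")
    df = df.astype(bool)
    rows = []
    for r1, r2 in itertools.combinations(df.columns, 2):
        pct = rate_pct(int((df[r1] == df[r2]).sum()), len(df))
        rows.append(
            {
                "reader_a": r1,
                "reader_b": r2,
                "n": len(df),
                "agreement_pct": pct,
                "meets_floor": pct >= acceptance_floor,
            }
        )
    overall = float(np.mean([r["agreement_pct"] for r in rows]))
    rows.append(
        {
            "reader_a": "overall",
            "reader_b": "",
            "n": len(df),
            "agreement_pct": overall,
            "meets_floor": overall >= acceptance_floor,
        }
    )
    return pd.DataFrame(rows)
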