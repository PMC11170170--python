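"""End-to-end screening pipeline and report rendering.

Mirrors the gated clinical screening flow: HLA typing is assessed for every
screened patient; tumor MAGE-A4 testing is evaluated only in HLA-eligible
patients; a patient is eligible overall when HLA-eligible *and* MAGE-A4
positive. The report gathers the per-stage summaries plus a provenance block
(inputs, config hash, version) so every number is reproducible from the
recorded inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from ._util import rate_pct, round_half_up
from .concordance import ConcordanceRecord, summarize_concordance
from .covariates import SeparationError, fit_logistic, or_table
from .hla import (
    DEFAULT_RULES,
    EligibilityRuleSet,
    PGroupTable,
    assess_genotype,
    builtin_pgroup_table,
    parse_genotype,
    summarize_eligibility,
)
from .ihc import (
    DEFAULT_CUTOFF,
    PositivityCutoff,
    archival_strata,
    frame_to_records,
    is_positive,
    pairwise_location_agreement,
    prevalence_by,
)

__all__ = ["ScreeningReport", "run_screen", "render_report", "load_config"]

logger = logging.getLogger("magescreen")


class ValidationError(ValueError):
    """Input file fails its schema (message carries the offending rows)."""


@dataclass
class ScreeningReport:
    eligibility: pd.DataFrame
    per_patient_hla: pd.DataFrame
    prevalence: dict            # covariate name -> prevalence frame
    location_agreement: Optional[dict]
    concordance: Optional[dict]
    covariate_ors: Optional[pd.DataFrame]
    combined: dict              # screened / hla_eligible / evaluable / positive / combined rate
    provenance: dict


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")


def _read_hla(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "genotype"], "hla_typing.csv")
    bad = []
    for i, g in enumerate(df["genotype"]):
        try:
            parse_genotype(str(g))
        except Exception as exc:  # collect all offending rows for the message
            bad.append(f"row {i + 2}: {exc}")
    if bad:
        raise ValidationError("hla_typing.csv: " + "; ".join(bad[:10]))
    return df


def _read_ihc(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["sample_id", "patient_id", "tumor_type", "pct0", "pct1", "pct2", "pct3"],
        "ihc.csv",
    )
    return df


def _rules_from_config(cfg: dict) -> EligibilityRuleSet:
    rules = cfg.get("rules", {})
    if not rules:
        return DEFAULT_RULES
    return EligibilityRuleSet(
        inclusion_groups=frozenset(rules.get("inclusion_groups",
                                             DEFAULT_RULES.inclusion_groups)),
        exclusion_groups=frozenset(rules.get("exclusion_groups",
                                             DEFAULT_RULES.exclusion_groups)),
        null_alleles_neutral=rules.get("null_alleles_neutral", True),
    )


def _cutoff_from_config(cfg: dict) -> PositivityCutoff:
    c = cfg.get("cutoff", {})
    if not c:
        return DEFAULT_CUTOFF
    return PositivityCutoff(
        min_pscore=float(c.get("min_pscore", 30.0)),
        min_intensity=int(c.get("min_intensity", 2)),
    )


def run_screen(config) -> ScreeningReport:
    """Run the full screening pipeline from a config mapping (or YAML path).

    Config keys: ``inputs`` (hla_typing, ihc, optional concordance),
    ``rules``, ``cutoff``, ``pgroup_table`` (path, else the builtin table),
    ``group_keys`` (demographic columns for the eligibility summary),
    ``covariate_terms`` (for the logistic OR table; skipped with a log line
    if the fit is not possible, e.g. separation).
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    inputs = cfg.get("inputs", {})
    if "hla_typing" not in inputs:
        raise ValidationError("config must name inputs.hla_typing")

    rules = _rules_from_config(cfg)
    cutoff = _cutoff_from_config(cfg)
    table = (
        PGroupTable.from_file(cfg["pgroup_table"])
        if cfg.get("pgroup_table")
        else builtin_pgroup_table()
    )
    group_keys = cfg.get("group_keys", ["race", "ethnicity"])

    hla_df = _read_hla(inputs["hla_typing"])
    group_keys = [k for k in group_keys if k in hla_df.columns]
    summary = summarize_eligibility(hla_df, rules, table, group_keys=group_keys)
    results = [assess_genotype(parse_genotype(str(g)), rules, table) for g in hla_df["genotype"]]
    per_patient = pd.DataFrame(
        {
            "patient_id": hla_df["patient_id"],
            "status": [r.status for r in results],
            "contribution_category": [r.contribution_category for r in results],
        }
    )
    eligible_ids = set(per_patient.loc[per_patient["status"] == "eligible", "patient_id"].astype(str))
    logger.info(
        "HLA stage: screened=%d eligible=%d indeterminate=%d",
        len(per_patient),
        len(eligible_ids),
        int((per_patient["status"] == "indeterminate").sum()),
    )

    prevalence: dict = {}
    location = None
    covariate_ors = None
    evaluable = positive = 0
    if inputs.get("ihc"):
        ihc_df = _read_ihc(inputs["ihc"])
        # gated flow: MAGE-A4 is tested only in HLA-eligible patients
        ihc_df = ihc_df[ihc_df["patient_id"].astype(str).isin(eligible_ids)]
        if ihc_df.empty:
            logger.info("IHC stage: no HLA-eligible patients with samples")
        else:
            records = frame_to_records(ihc_df)
            for key in ("tumor_type", "histology", "tissue_location"):
                prevalence[key] = prevalence_by(records, key, cutoff)
            if ihc_df["archival_years"].notna().all():
                prevalence["archival"] = archival_strata(records, [1, 5], cutoff)
            location = pairwise_location_agreement(records, cutoff).__dict__
            patient_prev = prevalence_by(records, None, cutoff)
            evaluable = int(patient_prev["n"].iloc[-1])
            positive = int(patient_prev["positive"].iloc[-1])
            logger.info("IHC stage: evaluable=%d positive=%d", evaluable, positive)
            terms = cfg.get("covariate_terms")
            if terms:
                ptab = ihc_df.copy()
                ptab["positive"] = [is_positive(r, cutoff) for r in records]
                try:
                    covariate_ors = or_table(
                        fit_logistic(ptab, terms, outcome="positive", mode="multivariate")
                    )
                except (SeparationError, ValueError) as exc:
                    logger.warning("covariate stage skipped: %s", exc)

    concordance_summary = None
    if inputs.get("concordance"):
        cdf = pd.read_csv(inputs["concordance"])
        _require_columns(cdf, ["sample_id", "reference_genotype", "assay_genotype"],
                         "concordance.csv")
        crecords = [
            ConcordanceRecord(
                sample_id=str(r.sample_id),
                reference=parse_genotype(str(r.reference_genotype)),
                assay=parse_genotype(str(r.assay_genotype)),
            )
            for r in cdf.itertuples()
        ]
        concordance_summary = summarize_concordance(crecords).display()

    screened = len(per_patient)
    combined = {
        "screened": screened,
        "hla_eligible": len(eligible_ids),
        "mage_evaluable": evaluable,
        "mage_positive": positive,
        "combined_eligible": positive,
        "combined_rate_pct": rate_pct(positive, screened) if screened else float("nan"),
    }

    canonical = json.dumps(cfg, sort_keys=True, default=str).encode()
    provenance = {
        "config_hash": hashlib.sha256(canonical).hexdigest(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "version": __version__,
        "seed": cfg.get("seed"),
    }
    return ScreeningReport(
        eligibility=summary,
        per_patient_hla=per_patient,
        prevalence=prevalence,
        location_agreement=location,
        concordance=concordance_summary,
        covariate_ors=covariate_ors,
        combined=combined,
        provenance=provenance,
    )


def _report_payload(report: ScreeningReport) -> dict:
    payload = {
        "eligibility": report.eligibility.to_dict(orient="records"),
        "prevalence": {k: v.to_dict(orient="records") for k, v in report.prevalence.items()},
        "location_agreement": report.location_agreement,
        "concordance": report.concordance,
        "covariate_ors": (
            report.covariate_ors.to_dict(orient="records")
            if report.covariate_ors is not None
            else None
        ),
        "combined": report.combined,
        "provenance": report.provenance,
    }
    return payload


def render_report(report: ScreeningReport, fmt: str = "json",
                  out_dir: Optional[Path] = None) -> dict:
    """Render a report deterministically (sorted keys; rounding applied only
    in the text rendering). Returns {filename: content}; writes the files
    when ``out_dir`` is given."""
    payload = _report_payload(report)
    if fmt == "json":
        files = {"report.json": json.dumps(payload, sort_keys=True, indent=2,
                                           default=_json_default) + "\n"}
    elif fmt == "csv-bundle":
        files = {"eligibility.csv": report.eligibility.to_csv(index=False)}
        for key, frame in report.prevalence.items():
            files[f"prevalence_{key}.csv"] = frame.to_csv(index=False)
        if report.covariate_ors is not None:
            files["covariate_ors.csv"] = report.covariate_ors.to_csv(index=False)
        files["combined.json"] = json.dumps(report.combined, sort_keys=True,
                                            indent=2, default=_json_default) + "\n"
    elif fmt == "text":
        files = {"report.txt": _render_text(report)}
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, content in files.items():
            (out_dir / name).write_text(content, encoding="utf-8")
    return files


def _json_default(o):
    if isinstance(o, (pd.Timestamp,)):
        return str(o)
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _render_text(report: ScreeningReport) -> str:
    lines = ["HLA / MAGE-A4 screening report", "=" * 32, "", "HLA eligibility"]
    for row in report.eligibility.to_dict(orient="records"):
        lines.append(
            f"  {row['group']}: {row['eligible']}/{row['screened']} "
            f"({row['eligibility_rate_pct_display']:.1f}%)"
        )
    for key, frame in report.prevalence.items():
        lines.append("")
        lines.append(f"MAGE-A4 prevalence by {key}")
        for row in frame.to_dict(orient="records"):
            if row["n"]:
                lines.append(
                    f"  {row['group']}: {row['positive']}/{row['n']} "
                    f"({round_half_up(row['rate_pct'], 0):.0f}%)"
                )
    if report.concordance:
        c = report.concordance
        lines += [
            "",
            "Typing concordance",
            f"  {c['concordant']}/{c['n']} concordant; "
            f"Clopper-Pearson lower {c['clopper_pearson_lower_pct']:.2f}%, "
            f"Wilson lower {c['wilson_lower_pct']:.2f}%",
        ]
    cmb = report.combined
    lines += [
        "",
        "Combined",
        f"  screened {cmb['screened']}, HLA-eligible {cmb['hla_eligible']}, "
        f"MAGE-A4 evaluable {cmb['mage_evaluable']}, positive {cmb['mage_positive']}",
    ]
    return "\n".join(lines) + "\n"
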