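"""HLA-A allele parsing, P-group resolution, and therapy eligibility calls.

TCR T cell therapies restricted to HLA-A*02 require each screened patient to
carry at least one *inclusion* allele (A*02:01, 02:02, 02:03, 02:06 or any
allele in their P groups — alleles identical over the peptide-binding
alpha1/alpha2 domains) and no *exclusion* allele (A*02:05P, excluded for TCR
alloreactivity). This module implements:

* WHO-nomenclature allele parsing (``A*02:01``, ``A*02:01:01:02N``),
* genotype-list strings with ambiguity alternatives (``a+b|c+d``),
* P-group lookup against an IMGT-dialect equivalence table,
* per-candidate and per-genotype eligibility with an explicit
  ``indeterminate`` status when ambiguous candidates disagree,
* the allele-contribution categories used to attribute eligibility to
  A*02:01P versus the other inclusion alleles, and
* cohort-level eligibility summaries grouped by demographics.

Null-expressed alleles (suffix ``N``) confer neither inclusion nor exclusion
by default: a protein that never reaches the cell surface can neither present
the target peptide nor trigger alloreactivity. This is a switch on
:class:`EligibilityRuleSet`.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from ._util import rate_pct, rate_pct_display

__all__ = [
    "HLAAllele",
    "GenotypeCall",
    "PGroupTable",
    "EligibilityRuleSet",
    "EligibilityResult",
    "HLAParseError",
    "parse_allele",
    "parse_genotype",
    "p_group",
    "assess_candidate",
    "assess_genotype",
    "contribution_category",
    "summarize_eligibility",
    "builtin_pgroup_table",
    "DEFAULT_RULES",
    "CONTRIBUTION_CATEGORIES",
]

EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

#: Eligible-patient contribution categories. ``A0201P`` absorbs any genotype
#: carrying an 02:01P allele (alone or combined with other inclusion alleles);
#: the ``*_exclusive`` categories name the exact inclusion-group set present
#: when 02:01P is absent; anything else multi-group is ``other_mixed``.
CONTRIBUTION_CATEGORIES = (
    "A0201P",
    "A0202_exclusive",
    "A0203_exclusive",
    "A0206_exclusive",
    "A0203_and_0206_exclusive",
    "other_mixed",
    "none",
)

_EXCLUSIVE_CATEGORY = {
    frozenset({"02:02P"}): "A0202_exclusive",
    frozenset({"02:03P"}): "A0203_exclusive",
    frozenset({"02:06P"}): "A0206_exclusive",
    frozenset({"02:03P", "02:06P"}): "A0203_and_0206_exclusive",
}


class HLAParseError(ValueError):
    """Raised for malformed allele or genotype strings."""


_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>[A-Z]+[0-9]*)\*(?P<fields>\d+(?::\d+)*)(?P<suffix>[A-Z])?$"
)


@dataclass(frozen=True)
class HLAAllele:
    """A parsed HLA allele name at two-to-four-field resolution.

    ``fields`` keeps the zero-padded tokens as written (``("02", "01")``);
    ``expression_suffix`` is the optional trailing expression character
    (``N`` null, ``L`` low, ``S`` secreted, ``C`` cytoplasmic, ``A`` aberrant,
    ``Q`` questionable) attached to the last field.
    """

    locus: str
    fields: tuple[str, ...]
    expression_suffix: Optional[str] = None
    raw: str = ""

    def __post_init__(self) -> None:
        if not self.locus:
            raise HLAParseError("empty locus")
        if len(self.fields) < 2:
            raise HLAParseError(
                f"high-resolution typing requires at least two fields, got {self.fields!r}"
            )
        if len(self.fields) > 4:
            raise HLAParseError(f"more than four fields in {self.fields!r}")
        if self.expression_suffix is not None and self.expression_suffix not in EXPRESSION_SUFFIXES:
            raise HLAParseError(
                f"unknown expression suffix {self.expression_suffix!r} "
                f"(allowed: {''.join(sorted(EXPRESSION_SUFFIXES))})"
            )

    @property
    def two_field(self) -> str:
        """Protein-level (two-field) projection without locus, e.g. ``02:01``."""
        return ":".join(self.fields[:2])

    @property
    def two_field_name(self) -> str:
        """Protein-level name with locus, e.g. ``A*02:01``."""
        return f"{self.locus}*{self.two_field}"

    @property
    def is_null(self) -> bool:
        return self.expression_suffix == "N"

    def format(self) -> str:
        """Canonical string form (round-trips through :func:`parse_allele`)."""
        return f"{self.locus}*{':'.join(self.fields)}{self.expression_suffix or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_allele(text: str) -> HLAAllele:
    """Parse a WHO-nomenclature allele string such as ``A*02:01:01:02N``.

    A leading ``HLA-`` prefix is accepted and dropped. At least two fields
    (protein-level resolution) are required; the expression suffix, if any,
    must be one of N/L/S/C/A/Q.
    """
    s = text.strip()
    m = _ALLELE_RE.match(s)
    if m is None:
        raise HLAParseError(f"malformed allele string: {text!r}")
    suffix = m.group("suffix")
    if suffix is not None and suffix not in EXPRESSION_SUFFIXES:
        raise HLAParseError(f"unknown expression suffix {suffix!r} in {text!r}")
    fields = tuple(m.group("fields").split(":"))
    if len(fields) < 2:
        raise HLAParseError(f"fewer than two fields in {text!r} (two-field typing required)")
    return HLAAllele(locus=m.group("locus"), fields=fields, expression_suffix=suffix, raw=s)


@dataclass(frozen=True)
class GenotypeCall:
    """One typing result: a non-empty list of unordered allele-pair candidates.

    A single candidate is an unambiguous call; several candidates record a
    typing ambiguity (alternative genotypes the assay could not distinguish).
    Homozygosity is the same allele twice in a candidate.
    """

    candidates: tuple[tuple[HLAAllele, HLAAllele], ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise HLAParseError("genotype call needs at least one candidate")
        for pair in self.candidates:
            if len(pair) != 2:
                raise HLAParseError(f"candidate must have exactly 2 alleles, got {len(pair)}")

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    def format(self) -> str:
        return "|".join("+".join(a.format() for a in pair) for pair in self.candidates)


def parse_genotype(text: str, locus: str = "A") -> GenotypeCall:
    """Parse a genotype-list string: ``+`` joins the two alleles of one
    candidate genotype, ``|`` separates alternative candidates.

    All alleles must be at ``locus``. Example:
    ``"A*02:01+A*68:01|A*02:135+A*69:02"`` is an ambiguous call with two
    candidate genotypes.
    """
    s = text.strip()
    if not s:
        raise HLAParseError("empty genotype string")
    candidates = []
    for i, cand in enumerate(s.split("|")):
        alleles = [parse_allele(tok) for tok in cand.split("+")]
        if len(alleles) != 2:
            raise HLAParseError(
                f"candidate {i + 1} ({cand!r}) has {len(alleles)} alleles; expected 2"
            )
        for a in alleles:
            if a.locus != locus:
                raise HLAParseError(f"allele {a.format()} is not at locus {locus}")
        candidates.append((alleles[0], alleles[1]))
    return GenotypeCall(candidates=tuple(candidates))


class PGroupTable:
    """Allele -> P-group equivalence mapping.

    P groups collect alleles with identical protein sequence over the
    alpha1/alpha2 peptide-binding domains; members present the same peptides
    and are interchangeable for eligibility. Lookup is total: an allele absent
    from the table forms a singleton group named after its two-field
    projection (rare alleles are neutral unless the table says otherwise).
    """

    def __init__(self, mapping: Mapping[str, str], source: str = "") -> None:
        self.source = source
        self._map: dict[str, str] = {}
        for name, group in mapping.items():
            if not group.endswith("P"):
                raise ValueError(f"P-group id {group!r} must end in 'P'")
            self._map[name] = group

    @classmethod
    def from_imgt(cls, lines: Iterable[str], source: str = "hla_nom_p") -> "PGroupTable":
        """Load the IMGT/HLA ``hla_nom_p.txt`` dialect.

        Records are ``locus*;allele1/allele2/...;group`` with ``#`` comment
        lines; a record with an empty group column lists an allele in no P
        group (left to the singleton fallback). Both the full allele names and
        their two-field projections are indexed (first occurrence wins on a
        projection collision).
        """
        mapping: dict[str, str] = {}
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(";")
            if len(parts) != 3:
                raise ValueError(f"malformed P-group record: {line!r}")
            locus_tok, alleles_tok, group = (p.strip() for p in parts)
            locus = locus_tok.rstrip("*")
            if not group:
                continue
            for name in alleles_tok.split("/"):
                allele = parse_allele(f"{locus}*{name}")
                full = allele.format()
                mapping.setdefault(full, group)
                mapping.setdefault(allele.two_field_name, group)
        return cls(mapping, source=source)

    @classmethod
    def from_file(cls, path) -> "PGroupTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_imgt(fh, source=str(path))

    def group(self, allele: HLAAllele) -> str:
        """P-group id for ``allele`` (e.g. ``"02:01P"``); never raises.

        Lookup tries the full name, then progressively shallower field
        truncations down to two fields (suffix kept, then dropped), then
        falls back to the singleton group ``<two-field>P``.
        """
        for depth in range(len(allele.fields), 1, -1):
            base = f"{allele.locus}*{':'.join(allele.fields[:depth])}"
            for key in ((base + allele.expression_suffix) if allele.expression_suffix else base,
                        base):
                hit = self._map.get(key)
                if hit is not None:
                    return hit
        return f"{allele.two_field}P"

    def __len__(self) -> int:
        return len(self._map)


def builtin_pgroup_table() -> PGroupTable:
    """The small packaged P-group table (A*02 eligibility groups plus common
    neutral alleles); covers the alleles the screening rules distinguish."""
    text = resources.files("magescreen.data").joinpath("pgroups_builtin.txt").read_text()
    return PGroupTable.from_imgt(text.splitlines(), source="builtin")


def p_group(allele: HLAAllele, table: PGroupTable) -> str:
    """P-group id of ``allele`` under ``table`` (total function)."""
    return table.group(allele)


@dataclass(frozen=True)
class EligibilityRuleSet:
    """Inclusion/exclusion P groups defining HLA eligibility.

    Defaults are the afami-cel / uza-cel criteria: at least one of
    02:01P/02:02P/02:03P/02:06P and no 02:05P. ``null_alleles_neutral``
    makes suffix-N alleles count for neither side.
    """

    inclusion_groups: frozenset[str] = frozenset({"02:01P", "02:02P", "02:03P", "02:06P"})
    exclusion_groups: frozenset[str] = frozenset({"02:05P"})
    null_alleles_neutral: bool = True

    def __post_init__(self) -> None:
        overlap = self.inclusion_groups & self.exclusion_groups
        if overlap:
            raise ValueError(f"inclusion and exclusion groups overlap: {sorted(overlap)}")


DEFAULT_RULES = EligibilityRuleSet()


@dataclass(frozen=True)
class EligibilityResult:
    status: str  # eligible | ineligible | indeterminate
    reason: str
    contribution_category: str  # one of CONTRIBUTION_CATEGORIES

    def __post_init__(self) -> None:
        if self.status not in ("eligible", "ineligible", "indeterminate"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.contribution_category not in CONTRIBUTION_CATEGORIES:
            raise ValueError(f"unknown category {self.contribution_category!r}")
        if self.status == "eligible" and self.contribution_category == "none":
            raise ValueError("eligible result must carry a contribution category")
        if self.status != "eligible" and self.contribution_category != "none":
            raise ValueError("non-eligible result cannot carry a contribution category")


def _effective_groups(
    pair: Sequence[HLAAllele], rules: EligibilityRuleSet, table: PGroupTable
) -> list[str]:
    """P groups of the expressed alleles (null alleles dropped if neutral)."""
    return [
        table.group(a)
        for a in pair
        if not (rules.null_alleles_neutral and a.is_null)
    ]


def assess_candidate(
    pair: Sequence[HLAAllele],
    rules: EligibilityRuleSet = DEFAULT_RULES,
    table: Optional[PGroupTable] = None,
) -> str:
    """Eligibility status of one unambiguous allele pair.

    Eligible iff at least one expressed allele falls in an inclusion group
    and none falls in an exclusion group; exclusion dominates inclusion.
    """
    table = table if table is not None else builtin_pgroup_table()
    groups = _effective_groups(pair, rules, table)
    if any(g in rules.exclusion_groups for g in groups):
        return "ineligible"
    if any(g in rules.inclusion_groups for g in groups):
        return "eligible"
    return "ineligible"


def contribution_category(
    pair: Sequence[HLAAllele],
    rules: EligibilityRuleSet = DEFAULT_RULES,
    table: Optional[PGroupTable] = None,
) -> str:
    """Which inclusion allele(s) make an eligible pair eligible.

    02:01P dominates (a patient carrying 02:01P is ``A0201P`` even when a
    second inclusion allele is present); otherwise the category is named by
    the exact set of inclusion groups present, with unanticipated multi-group
    combinations mapped to ``other_mixed``.
    """
    table = table if table is not None else builtin_pgroup_table()
    if assess_candidate(pair, rules, table) != "eligible":
        raise ValueError(f"contribution_category called on ineligible pair "
                         f"{[a.format() for a in pair]}")
    groups = set(_effective_groups(pair, rules, table))
    inc = frozenset(groups & rules.inclusion_groups)
    if "02:01P" in inc:
        return "A0201P"
    return _EXCLUSIVE_CATEGORY.get(inc, "other_mixed")


def assess_genotype(
    call: GenotypeCall,
    rules: EligibilityRuleSet = DEFAULT_RULES,
    table: Optional[PGroupTable] = None,
) -> EligibilityResult:
    """Eligibility of a possibly ambiguous call, by candidate unanimity.

    If every candidate genotype agrees on the status, that status is
    returned; discordant candidates give ``indeterminate`` (in screening such
    calls go back for ambiguity resolution rather than being decided). The
    contribution category is computed for eligible results only; candidates
    that agree on eligibility but not on category are reported
    ``other_mixed``.
    """
    table = table if table is not None else builtin_pgroup_table()
    statuses = [assess_candidate(pair, rules, table) for pair in call.candidates]
    if len(set(statuses)) > 1:
        detail = "; ".join(
            f"{'+'.join(a.format() for a in pair)}:{st}"
            for pair, st in zip(call.candidates, statuses)
        )
        return EligibilityResult(
            status="indeterminate",
            reason=f"ambiguous candidates disagree on eligibility ({detail})",
            contribution_category="none",
        )
    status = statuses[0]
    if status != "eligible":
        return EligibilityResult(
            status=status,
            reason="no candidate satisfies the inclusion rule"
            if status == "ineligible"
            else "",
            contribution_category="none",
        )
    categories = {contribution_category(pair, rules, table) for pair in call.candidates}
    category = categories.pop() if len(categories) == 1 else "other_mixed"
    return EligibilityResult(
        status="eligible",
        reason="at least one inclusion allele and no exclusion allele",
        contribution_category=category,
    )


_EXCLUSIVE_NON_0201 = (
    "A0202_exclusive",
    "A0203_exclusive",
    "A0206_exclusive",
    "A0203_and_0206_exclusive",
    "other_mixed",
)


def summarize_eligibility(
    cohort: pd.DataFrame,
    rules: EligibilityRuleSet = DEFAULT_RULES,
    table: Optional[PGroupTable] = None,
    group_keys: Sequence[str] = (),
    genotype_column: str = "genotype",
) -> pd.DataFrame:
    """Cohort eligibility summary, per demographic group and overall.

    ``cohort`` needs a genotype column (GL-subset strings or
    :class:`GenotypeCall`) plus any grouping columns; missing demographic
    values are pooled as ``"Not recorded"``. Each output row carries screened
    / eligible / indeterminate counts, the eligibility rate (full precision
    and display-rounded to one decimal, half-up), per-category counts, and
    ``non_a0201p_share_pct`` — the share of eligible patients whose
    eligibility does not involve an 02:01P allele (the statistic behind the
    per-ethnicity contribution percentages).
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    table = table if table is not None else builtin_pgroup_table()

    df = cohort.copy()
    calls = [
        g if isinstance(g, GenotypeCall) else parse_genotype(str(g))
        for g in df[genotype_column]
    ]
    results = [assess_genotype(c, rules, table) for c in calls]
    df["_status"] = [r.status for r in results]
    df["_category"] = [r.contribution_category for r in results]

    def _one_group(sub: pd.DataFrame, label) -> dict:
        screened = len(sub)
        eligible = int((sub["_status"] == "eligible").sum())
        indeterminate = int((sub["_status"] == "indeterminate").sum())
        row: dict = {
            "group": label,
            "screened": screened,
            "eligible": eligible,
            "indeterminate": indeterminate,
            "eligibility_rate_pct": rate_pct(eligible, screened),
            "eligibility_rate_pct_display": rate_pct_display(eligible, screened, 1),
        }
        for cat in CONTRIBUTION_CATEGORIES[:-1]:
            row[f"n_{cat}"] = int((sub["_category"] == cat).sum())
        n_excl = int(sub["_category"].isin(_EXCLUSIVE_NON_0201).sum())
        row["non_a0201p_share_pct"] = (
            rate_pct(n_excl, eligible) if eligible else float("nan")
        )
        return row

    rows = []
    if group_keys:
        keyframe = df[list(group_keys)].astype(object).fillna("Not recorded")
        labels = keyframe.apply(lambda r: " / ".join(str(v) for v in r), axis=1)
        for label in labels.unique():
            rows.append(_one_group(df[labels == label], label))
    rows.append(_one_group(df, "Overall"))
    return pd.DataFrame(rows)
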