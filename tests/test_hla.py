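"""Allele/genotype parsing, P-group resolution, and eligibility logic."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from magescreen.hla import (
    CONTRIBUTION_CATEGORIES,
    EligibilityRuleSet,
    HLAParseError,
    PGroupTable,
    assess_candidate,
    assess_genotype,
    contribution_category,
    p_group,
    parse_allele,
    parse_genotype,
    summarize_eligibility,
)


class TestParseAllele:
    @pytest.mark.parametrize(
        "text, locus, fields, suffix",
        [
            ("A*02:01", "A", ("02", "01"), None),
            ("A*02:135", "A", ("02", "135"), None),
            ("A*02:01:01:02N", "A", ("02", "01", "01", "02"), "N"),
            ("HLA-A*24:02", "A", ("24", "02"), None),
            ("A*01:01:01:02L", "A", ("01", "01", "01", "02"), "L"),
            ("B*07:02", "B", ("07", "02"), None),
        ],
    )
    def test_examples(self, text, locus, fields, suffix):
        a = parse_allele(text)
        assert (a.locus, a.fields, a.expression_suffix) == (locus, fields, suffix)

    @pytest.mark.parametrize(
        "bad",
        ["", "A*02", "02:01", "A-02:01", "A*02:01X", "A*02:01:01:02:03", "A*+B"],
    )
    def test_malformed(self, bad):
        with pytest.raises(HLAParseError):
            parse_allele(bad)

    def test_two_field_projection_stable_under_reparse(self):
        a = parse_allele("A*02:01:01:02N")
        assert a.two_field == "02:01"
        assert parse_allele(a.format()).two_field == "02:01"

    @given(
        st.sampled_from("AB"),
        st.lists(st.integers(1, 999), min_size=2, max_size=4),
        st.sampled_from([None, "N", "L", "Q"]),
    )
    @settings(derandomize=True, max_examples=60)
    def test_round_trip(self, locus, nums, suffix):
        text = f"{locus}*{':'.join(f'{n:02d}' for n in nums)}{suffix or ''}"
        a = parse_allele(text)
        assert a.format() == text
        assert parse_allele(a.format()) == parse_allele(text)


class TestParseGenotype:
    def test_unambiguous(self):
        call = parse_genotype("A*02:01+A*03:01")
        assert not call.ambiguous and len(call.candidates) == 1

    def test_ambiguous_two_candidates(self):
        call = parse_genotype("A*02:01+A*68:01|A*02:135+A*69:02")
        assert call.ambiguous and len(call.candidates) == 2

    def test_homozygous(self):
        call = parse_genotype("A*02:01+A*02:01")
        a, b = call.candidates[0]
        assert a == b and not call.ambiguous

    @pytest.mark.parametrize(
        "bad",
        ["", "A*02:01", "A*02:01+A*03:01+A*11:01", "A*02:01+B*07:02"],
    )
    def test_malformed(self, bad):
        with pytest.raises(HLAParseError):
            parse_genotype(bad)

    def test_round_trip(self):
        text = "A*02:01+A*68:01|A*02:135+A*69:02"
        assert parse_genotype(text).format() == text


class TestPGroup:
    @pytest.mark.parametrize(
        "name, group",
        [
            ("A*02:09", "02:01P"),
            ("A*02:642", "02:01P"),
            ("A*02:01:01:01", "02:01P"),
            ("A*02:05", "02:05P"),
            ("A*97:99", "97:99P"),   # unlisted -> singleton of two-field projection
            ("A*02:135", "02:135P"),
        ],
    )
    def test_lookup(self, pgroups, name, group):
        assert p_group(parse_allele(name), pgroups) == group

    def test_two_field_projection_same_group_for_members(self, pgroups):
        # projecting a listed four-field member to two fields keeps the group
        assert p_group(parse_allele("A*02:01"), pgroups) == p_group(
            parse_allele("A*02:01:01:01"), pgroups
        )

    def test_group_ids_end_in_p(self, pgroups):
        for name in ["A*02:01", "A*03:01", "A*99:99"]:
            assert p_group(parse_allele(name), pgroups).endswith("P")

    def test_from_imgt_dialect(self):
        table = PGroupTable.from_imgt(
            ["# comment", "", "A*;02:01:01:01/02:09;02:01P", "A*;02:351;"]
        )
        assert table.group(parse_allele("A*02:09")) == "02:01P"
        # empty group column -> singleton fallback
        assert table.group(parse_allele("A*02:351")) == "02:351P"

    def test_bad_group_id_rejected(self):
        with pytest.raises(ValueError):
            PGroupTable({"A*02:01": "02:01"})


class TestAssessCandidate:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("A*02:01", "A*01:01"), "eligible"),
            (("A*02:01", "A*02:05"), "ineligible"),   # exclusion dominates
            (("A*01:01", "A*03:01"), "ineligible"),   # no inclusion allele
            (("A*02:09", "A*03:01"), "eligible"),     # via the 02:01 P group
            (("A*02:05", "A*02:05"), "ineligible"),
        ],
    )
    def test_rule(self, pgroups, rules, pair, expected):
        alleles = tuple(parse_allele(p) for p in pair)
        assert assess_candidate(alleles, rules, pgroups) == expected

    def test_null_inclusion_allele_is_neutral(self, pgroups, rules):
        pair = (parse_allele("A*02:01:01:02N"), parse_allele("A*03:01"))
        # N-suffixed allele expresses no protein: cannot present the peptide
        assert assess_candidate(pair, rules, pgroups) == "ineligible"

    def test_null_exclusion_allele_is_neutral(self, pgroups, rules):
        pair = (parse_allele("A*02:01"), parse_allele("A*02:05:01N"))
        assert assess_candidate(pair, rules, pgroups) == "eligible"

    def test_null_neutrality_switch(self, pgroups):
        strict = EligibilityRuleSet(null_alleles_neutral=False)
        pair = (parse_allele("A*02:01"), parse_allele("A*02:05:01N"))
        assert assess_candidate(pair, strict, pgroups) == "ineligible"

    @given(st.sampled_from(["A*02:01", "A*02:02", "A*02:03", "A*02:06", "A*02:09",
                            "A*01:01", "A*03:01", "A*24:02", "A*97:99"]))
    @settings(derandomize=True, max_examples=20)
    def test_exclusion_dominance(self, pgroups, rules, other):
        # adding an exclusion allele never yields eligible
        pair = (parse_allele(other), parse_allele("A*02:05"))
        assert assess_candidate(pair, rules, pgroups) == "ineligible"

    @given(st.sampled_from(["A*01:01", "A*03:01", "A*24:02", "A*02:06"]))
    @settings(derandomize=True, max_examples=10)
    def test_inclusion_never_revokes(self, pgroups, rules, other):
        # an eligible pair stays eligible when the partner is any non-exclusion allele
        pair = (parse_allele("A*02:01"), parse_allele(other))
        assert assess_candidate(pair, rules, pgroups) == "eligible"

    def test_rules_disjointness_enforced(self):
        with pytest.raises(ValueError):
            EligibilityRuleSet(
                inclusion_groups=frozenset({"02:01P"}),
                exclusion_groups=frozenset({"02:01P"}),
            )


class TestContributionCategory:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("A*02:01", "A*02:06"), "A0201P"),  # 02:01P dominates
            (("A*02:09", "A*01:01"), "A0201P"),  # via P group
            (("A*02:03", "A*02:06"), "A0203_and_0206_exclusive"),
            (("A*02:02", "A*01:01"), "A0202_exclusive"),
            (("A*02:03", "A*03:01"), "A0203_exclusive"),
            (("A*02:06", "A*02:06"), "A0206_exclusive"),
            (("A*02:02", "A*02:03"), "other_mixed"),  # undefined combination
        ],
    )
    def test_examples(self, pgroups, rules, pair, expected):
        alleles = tuple(parse_allele(p) for p in pair)
        assert contribution_category(alleles, rules, pgroups) == expected

    def test_ineligible_pair_is_contract_violation(self, pgroups, rules):
        pair = (parse_allele("A*01:01"), parse_allele("A*03:01"))
        with pytest.raises(ValueError):
            contribution_category(pair, rules, pgroups)


class TestAssessGenotype:
    def test_unambiguous_matches_candidate(self, pgroups, rules):
        call = parse_genotype("A*02:01+A*01:01")
        res = assess_genotype(call, rules, pgroups)
        assert res.status == assess_candidate(call.candidates[0], rules, pgroups)
        assert res.contribution_category == "A0201P"

    def test_discordant_candidates_are_indeterminate(self, pgroups, rules):
        # candidate 1 eligible (02:01), candidate 2 ineligible (both neutral)
        call = parse_genotype("A*02:01+A*68:01|A*02:135+A*69:02")
        statuses = {assess_candidate(p, rules, pgroups) for p in call.candidates}
        assert statuses == {"eligible", "ineligible"}
        res = assess_genotype(call, rules, pgroups)
        assert res.status == "indeterminate"
        assert res.contribution_category == "none"
        assert "02:135" in res.reason

    def test_unanimous_ineligible(self, pgroups, rules):
        call = parse_genotype("A*01:01+A*03:01|A*01:01+A*24:02")
        assert assess_genotype(call, rules, pgroups).status == "ineligible"

    def test_unanimous_eligible_category_agreement(self, pgroups, rules):
        call = parse_genotype("A*02:01+A*01:01|A*02:09+A*01:01")
        res = assess_genotype(call, rules, pgroups)
        assert (res.status, res.contribution_category) == ("eligible", "A0201P")

    def test_category_disagreement_falls_to_other_mixed(self, pgroups, rules):
        call = parse_genotype("A*02:01+A*01:01|A*02:02+A*01:01")
        res = assess_genotype(call, rules, pgroups)
        assert (res.status, res.contribution_category) == ("eligible", "other_mixed")


class TestSummarizeEligibility:
    def _cohort(self, genotypes, **cols):
        df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(len(genotypes))],
                           "genotype": genotypes})
        for k, v in cols.items():
            df[k] = v
        return df

    def test_hand_enumerated_fixture(self, pgroups, rules):
        # 3 eligible of 10 by construction
        genotypes = (
            ["A*02:01+A*01:01", "A*02:02+A*03:01", "A*02:06+A*24:02"]
            + ["A*01:01+A*03:01"] * 5
            + ["A*02:01+A*02:05"] * 2
        )
        out = summarize_eligibility(self._cohort(genotypes), rules, pgroups)
        overall = out.iloc[-1]
        assert overall["screened"] == 10
        assert overall["eligible"] == 3
        assert overall["eligibility_rate_pct_display"] == 30.0

    def test_single_eligible_patient(self, pgroups, rules):
        out = summarize_eligibility(self._cohort(["A*02:01+A*01:01"]), rules, pgroups)
        assert out.iloc[-1]["eligibility_rate_pct"] == 100.0

    def test_partition_of_eligible_counts(self, pgroups, rules):
        genotypes = [
            "A*02:01+A*02:06", "A*02:02+A*01:01", "A*02:03+A*02:06",
            "A*02:06+A*03:01", "A*02:02+A*02:03", "A*02:01+A*02:01",
            "A*01:01+A*03:01", "A*02:01+A*02:05",
            "A*02:01+A*68:01|A*02:135+A*69:02",
        ]
        out = summarize_eligibility(self._cohort(genotypes), rules, pgroups)
        overall = out.iloc[-1]
        category_total = sum(
            overall[f"n_{cat}"] for cat in CONTRIBUTION_CATEGORIES[:-1]
        )
        assert category_total == overall["eligible"] == 6
        assert overall["indeterminate"] == 1

    def test_missing_demographics_pool_as_not_recorded(self, pgroups, rules):
        df = self._cohort(
            ["A*02:01+A*01:01", "A*01:01+A*03:01"], race=["White", None]
        )
        out = summarize_eligibility(df, rules, pgroups, group_keys=["race"])
        assert "Not recorded" in set(out["group"])

    def test_non_a0201p_share(self, pgroups, rules):
        genotypes = ["A*02:01+A*01:01", "A*02:02+A*01:01", "A*02:03+A*02:06",
                     "A*02:02+A*02:03"]
        out = summarize_eligibility(self._cohort(genotypes), rules, pgroups)
        assert out.iloc[-1]["non_a0201p_share_pct"] == pytest.approx(75.0)

    def test_empty_cohort_errors(self, pgroups, rules):
        with pytest.raises(ValueError):
            summarize_eligibility(pd.DataFrame(columns=["patient_id", "genotype"]),
                                  rules, pgroups)
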