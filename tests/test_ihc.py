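"""P-score computation, positivity calls, prevalence and agreement summaries."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from magescreen.ihc import (
    DEFAULT_CUTOFF,
    LEGACY_CUTOFF,
    PositivityCutoff,
    StainingRecord,
    archival_strata,
    frame_to_records,
    is_positive,
    p_score,
    pairwise_location_agreement,
    prevalence_by,
    reader_concordance,
    records_to_frame,
)
from conftest import make_record


def record_from_pcts(pct0, pct1, pct2, pct3, **kw):
    defaults = dict(sample_id="S1", patient_id="P1", tumor_type="SyS")
    defaults.update(kw)
    return StainingRecord(pct_intensity=(pct0, pct1, pct2, pct3), **defaults)


class TestPScore:
    @pytest.mark.parametrize(
        "pcts, expected",
        [
            ((0, 3, 60, 37), 97.0),    # strong staining: 60% at 2+, 37% at 3+
            ((0, 100, 0, 0), 0.0),     # all 1+ counts nothing
            ((70, 0, 30, 0), 30.0),
        ],
    )
    def test_examples(self, pcts, expected):
        assert p_score(record_from_pcts(*pcts)) == expected

    @given(st.floats(0, 60), st.floats(0, 1))
    @settings(derandomize=True, max_examples=40)
    def test_invariant_to_zero_one_split(self, below, frac):
        # the split of the sub-threshold mass between 0 and 1+ is irrelevant
        rest = 100.0 - below
        r1 = record_from_pcts(below * frac, below * (1 - frac), 0.6 * rest, 0.4 * rest)
        r2 = record_from_pcts(below, 0.0, 0.6 * rest, 0.4 * rest)
        assert p_score(r1) == pytest.approx(p_score(r2), abs=1e-9)

    def test_legacy_intensity_floor(self):
        rec = record_from_pcts(50, 30, 10, 10)
        assert p_score(rec, min_intensity=1) == 50.0
        assert p_score(rec, min_intensity=2) == 20.0

    @pytest.mark.parametrize(
        "pcts", [(-1, 1, 60, 40), (0, 0, 30, 30), (0, 0, 60, 41)]
    )
    def test_invalid_records_rejected(self, pcts):
        with pytest.raises(ValueError):
            record_from_pcts(*pcts)

    def test_negative_archival_rejected(self):
        with pytest.raises(ValueError):
            record_from_pcts(0, 0, 60, 40, archival_years=-1.0)


class TestIsPositive:
    def test_cutoff_boundary_inclusive(self):
        assert is_positive(make_record(p_score=30.0))

    def test_below_cutoff(self):
        assert not is_positive(make_record(p_score=29.5))

    def test_high_score_positive(self):
        assert is_positive(make_record(p_score=76.0))

    def test_legacy_preset(self):
        rec = record_from_pcts(85, 15, 0, 0)
        assert is_positive(rec, LEGACY_CUTOFF)
        assert not is_positive(rec, DEFAULT_CUTOFF)

    @given(st.floats(0, 70), st.floats(0, 30))
    @settings(derandomize=True, max_examples=40)
    def test_monotone_in_staining(self, score, boost):
        # moving mass from 0/1+ into 2+/3+ never flips positive -> negative
        base = make_record(p_score=score)
        boosted = make_record(p_score=min(100.0, score + boost))
        if is_positive(base):
            assert is_positive(boosted)

    def test_degenerate_cutoffs(self):
        any_staining = make_record(p_score=0.5)
        assert is_positive(any_staining, PositivityCutoff(0.0, 2))
        assert not is_positive(make_record(p_score=100.0), PositivityCutoff(100.0, 3))


def _cohort_fixture(n_pos, n_neg, tumor_type, start=0):
    records = []
    for i in range(n_pos):
        records.append(make_record(sample_id=f"{tumor_type}s{start + i}",
                                   patient_id=f"{tumor_type}p{start + i}",
                                   tumor_type=tumor_type, p_score=60.0))
    for i in range(n_neg):
        j = start + n_pos + i
        records.append(make_record(sample_id=f"{tumor_type}s{j}",
                                   patient_id=f"{tumor_type}p{j}",
                                   tumor_type=tumor_type, p_score=0.0))
    return records


class TestPrevalence:
    def test_printed_style_rates(self):
        records = _cohort_fixture(140, 61, "SyS") + _cohort_fixture(6, 64, "gastric")
        out = prevalence_by(records, "tumor_type")
        by_group = out.set_index("group")
        assert by_group.loc["SyS", "positive"] == 140
        assert by_group.loc["SyS", "rate_pct_display"] == 70
        # 6/70 = 8.57% rounds half-up to 9%
        assert by_group.loc["gastric", "rate_pct_display"] == 9

    def test_all_negative_group(self):
        out = prevalence_by(_cohort_fixture(0, 5, "gastric"), "tumor_type")
        row = out.set_index("group").loc["gastric"]
        assert row["rate_pct"] == 0.0 and row["median_p_score"] == 0.0

    def test_conserved_under_refinement(self):
        recs = []
        for i in range(20):
            recs.append(
                make_record(sample_id=f"s{i}", patient_id=f"p{i}", tumor_type="NSCLC",
                            p_score=60.0 if i % 3 == 0 else 0.0,
                            histology="SCC" if i % 2 else "AC")
            )
        overall = prevalence_by(recs, "tumor_type").set_index("group")
        refined = prevalence_by(recs, "histology").set_index("group")
        assert (refined.loc["SCC", "positive"] + refined.loc["AC", "positive"]
                == overall.loc["NSCLC", "positive"])

    def test_patient_mode_any_positive_sample(self):
        recs = [
            make_record(sample_id="s1", patient_id="p1", p_score=60.0),
            make_record(sample_id="s2", patient_id="p1", p_score=0.0),
            make_record(sample_id="s3", patient_id="p2", p_score=0.0),
        ]
        patients = prevalence_by(recs, "tumor_type", unit="patient").iloc[-1]
        samples = prevalence_by(recs, "tumor_type", unit="sample").iloc[-1]
        assert (patients["n"], patients["positive"]) == (2, 1)
        assert (samples["n"], samples["positive"]) == (3, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            prevalence_by([], "tumor_type")


class TestLocationAgreement:
    def _dual(self, pid, primary_score, met_score):
        return [
            make_record(sample_id=f"{pid}a", patient_id=pid, p_score=primary_score,
                        tissue_location="primary"),
            make_record(sample_id=f"{pid}b", patient_id=pid, p_score=met_score,
                        tissue_location="metastatic"),
        ]

    def test_sixteen_patients_thirteen_agree(self):
        records = []
        for i in range(10):                      # both positive
            records += self._dual(f"pp{i}", 60, 60)
        for i in range(3):                       # both negative
            records += self._dual(f"nn{i}", 0, 5)
        for i in range(3):                       # discordant
            records += self._dual(f"dx{i}", 60, 0)
        out = pairwise_location_agreement(records)
        assert (out.n_dual, out.n_agree) == (16, 13)
        assert out.pct_display == 81.0

    def test_single_both_positive(self):
        out = pairwise_location_agreement(self._dual("p", 60, 60))
        assert (out.n_dual, out.n_agree, out.fraction) == (1, 1, 1.0)

    def test_discordant_counted(self):
        out = pairwise_location_agreement(self._dual("p", 60, 0))
        assert (out.n_dual, out.n_agree) == (1, 0)

    def test_single_location_patients_excluded(self):
        records = self._dual("p", 60, 60) + [
            make_record(sample_id="q1", patient_id="q", p_score=60,
                        tissue_location="primary")
        ]
        out = pairwise_location_agreement(records)
        assert out.n_dual == 1 and out.n_excluded == 1

    def test_location_maximum_used(self):
        records = self._dual("p", 0, 60) + [
            make_record(sample_id="pc", patient_id="p", p_score=80,
                        tissue_location="primary")
        ]
        # second primary sample is positive -> primary location positive
        assert pairwise_location_agreement(records).n_agree == 1


class TestArchivalStrata:
    def _records(self, years):
        return [
            make_record(sample_id=f"s{i}", patient_id=f"p{i}",
                        p_score=60.0 if i % 2 else 0.0, archival_years=y)
            for i, y in enumerate(years)
        ]

    def test_partition_conserves_counts(self):
        recs = self._records([0.1, 0.5, 1.0, 2.0, 4.9, 5.0, 7.5, 12.0])
        out = archival_strata(recs, [1, 5])
        assert out["n"].sum() == len(recs)
        assert list(out["group"]) == ["[0, 1)", "[1, 5)", "[5, inf)"]

    def test_boundary_goes_to_upper_stratum(self):
        out = archival_strata(self._records([1.0]), [1, 5])
        assert out.set_index("group").loc["[1, 5)", "n"] == 1

    def test_non_increasing_breaks_rejected(self):
        with pytest.raises(ValueError):
            archival_strata(self._records([1.0]), [5, 1])

    def test_missing_archival_time_rejected(self):
        with pytest.raises(ValueError):
            archival_strata([make_record(p_score=0.0)], [1, 5])


class TestReaderConcordance:
    def test_identical_readers(self):
        calls = {"r1": [True, False, True], "r2": [True, False, True]}
        out = reader_concordance(calls)
        assert out.iloc[0]["agreement_pct"] == 100.0

    def test_eight_of_ten_at_floor(self):
        calls = {"r1": [True] * 10, "r2": [True] * 8 + [False] * 2}
        out = reader_concordance(calls, acceptance_floor=80.0)
        assert out.iloc[0]["agreement_pct"] == 80.0
        assert bool(out.iloc[0]["meets_floor"])

    def test_three_readers_hand_enumerated(self):
        calls = {
            "r1": [True, True, False, False],
            "r2": [True, False, False, False],   # differs from r1 on sample 2
            "r3": [True, True, True, False],     # differs from r1 on sample 3
        }
        out = reader_concordance(calls).set_index(["reader_a", "reader_b"])
        assert out.loc[("r1", "r2"), "agreement_pct"] == 75.0
        assert out.loc[("r1", "r3"), "agreement_pct"] == 75.0
        assert out.loc[("r2", "r3"), "agreement_pct"] == 50.0
        assert out.loc[("overall", ""), "agreement_pct"] == pytest.approx(200 / 3)

    def test_mismatched_sample_sets_rejected(self):
        calls = {
            "r1": pd.Series([True, False], index=["a", "b"]),
            "r2": pd.Series([True], index=["a"]),
        }
        with pytest.raises(ValueError):
            reader_concordance(calls)


def test_frame_round_trip():
    recs = [make_record(sample_id="s1", patient_id="p1", p_score=40.0,
                        patient_age=55.0, archival_years=2.0)]
    back = frame_to_records(records_to_frame(recs))
    assert back == recs
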