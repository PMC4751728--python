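"""Alignment, error classification and per-position profiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampbench import (
    PROTEIN_G_AMPLICON,
    AlignmentResult,
    ConsensusRecord,
    CopiesModel,
    align_local,
    build_profile,
    classify_errors,
    revcomp,
    tag_error_probability,
)
from ampbench.error_profiling import ERROR_TYPES, ScoringParams

from .conftest import make_pairs
from .oracles import sw_gotoh_score

REF = PROTEIN_G_AMPLICON


def _sub(seq, pos0, base):
    assert seq[pos0] != base
    return seq[:pos0] + base + seq[pos0 + 1 :]


class TestAlignLocal:
    def test_reference_aligns_to_itself(self):
        aln = align_local(REF, REF)
        assert aln.score == 88
        assert "-" not in aln.aligned_ref and "-" not in aln.aligned_query
        assert (aln.ref_start, aln.ref_end) == (1, 88)

    def test_single_interior_substitution_scores_86(self):
        query = _sub(REF, 40, "A" if REF[40] != "A" else "C")
        aln = align_local(query, REF)
        assert aln.score == 86  # 87 matches - 1 mismatch
        assert sw_gotoh_score(query, REF) == 86

    def test_single_deletion_scores_86(self):
        query = REF[:40] + REF[41:]  # length-1 gap costs gap_open only
        aln = align_local(query, REF)
        assert aln.score == 86  # 87 matches - 1 gap open
        assert sw_gotoh_score(query, REF) == 86

    def test_empty_sequence_is_domain_error(self):
        with pytest.raises(ValueError):
            align_local("", REF)

    def test_no_positive_segment_gives_empty_alignment(self):
        aln = align_local("C", "A")
        assert aln.score == 0 and aln.ref_end < aln.ref_start

    def test_tie_break_prefers_fewer_gaps_and_wider_span(self):
        # a near-end substitution must stay aligned, not be clipped away
        query = _sub(REF, 2, "A" if REF[2] != "A" else "C")
        aln = align_local(query, REF)
        assert (aln.ref_start, aln.ref_end) == (1, 88)
        assert "-" not in aln.aligned_ref

    def test_scoring_params_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScoringParams(match=-1.0)
        with pytest.raises(ValueError):
            ScoringParams(gap_open=-0.2, gap_extend=-0.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=12),
        st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_score_matches_dp_oracle(self, query, reference):
        assert align_local(query, reference).score == pytest.approx(
            sw_gotoh_score(query, reference)
        )


class TestClassifyErrors:
    @pytest.mark.parametrize(
        "ref_base, obs_base, expected",
        [
            ("A", "G", "transition"), ("G", "A", "transition"),
            ("C", "T", "transition"), ("T", "C", "transition"),
            ("A", "C", "transversion"), ("A", "T", "transversion"),
            ("G", "C", "transversion"), ("G", "T", "transversion"),
        ],
    )
    def test_substitution_table(self, ref_base, obs_base, expected):
        aln = AlignmentResult(ref_base, obs_base, -1.0, 1, 1)
        (event,) = classify_errors(aln)
        assert event.type == expected

    def test_deletion_at_reference_position(self):
        aln = AlignmentResult("ACG", "A-G", 1.0, 5, 7)
        (event,) = classify_errors(aln)
        assert (event.position, event.type, event.ref_base, event.obs_base) == (6, "deletion", "C", "-")

    def test_insertion_assigned_to_preceding_position(self):
        aln = AlignmentResult("AC-G", "ACTG", 2.0, 5, 7)
        (event,) = classify_errors(aln)
        assert (event.position, event.type) == (6, "insertion")

    def test_insertion_before_first_base_is_position_zero(self):
        aln = AlignmentResult("-AC", "TAC", 1.0, 1, 2)
        assert classify_errors(aln)[0].position == 0

    def test_gap_run_yields_single_base_events(self):
        aln = AlignmentResult("ACGTA", "A---A", -0.5, 1, 5)
        events = classify_errors(aln)
        assert [e.type for e in events] == ["deletion"] * 3
        assert [e.position for e in events] == [2, 3, 4]

    def test_n_is_transversion_by_default_and_separable(self):
        aln = AlignmentResult("A", "N", -1.0, 1, 1)
        assert classify_errors(aln)[0].type == "transversion"
        assert classify_errors(aln, n_policy="separate")[0].type == "n_call"

    def test_event_conservation(self):
        # mismatch columns = transitions + transversions; gap columns = indels
        rng = np.random.default_rng(4)
        for _ in range(200):
            query = "".join(rng.choice(list("ACGTN"), size=30))
            ref = "".join(rng.choice(list("ACGT"), size=30))
            aln = align_local(query, ref)
            events = classify_errors(aln)
            cols = list(zip(aln.aligned_ref, aln.aligned_query))
            n_mismatch = sum(a != b and "-" not in (a, b) for a, b in cols)
            n_gap = sum("-" in (a, b) for a, b in cols)
            by_type = {t: sum(e.type == t for e in events) for t in ERROR_TYPES}
            assert by_type["transition"] + by_type["transversion"] == n_mismatch
            assert by_type["insertion"] + by_type["deletion"] == n_gap


class TestErrorProfile:
    def test_identical_records_have_zero_rates(self):
        profile = build_profile([REF] * 20, REF)
        assert profile.counts.sum() == 0
        assert profile.coverage[1:].tolist() == [20] * 88
        assert profile.overall_rate() == 0.0

    def test_profile_additivity(self):
        queries_a = [_sub(REF, 10, "A" if REF[10] != "A" else "C")] * 3 + [REF] * 5
        queries_b = [_sub(REF, 50, "T" if REF[50] != "T" else "G")] * 2 + [REF] * 4
        pa = build_profile(queries_a, REF)
        pb = build_profile(queries_b, REF)
        merged = pa + pb
        both = build_profile(queries_a + queries_b, REF)
        assert np.array_equal(merged.counts, both.counts)
        assert np.array_equal(merged.coverage, both.coverage)

    def test_unalignable_records_excluded_from_coverage(self):
        junk = "T" * 88 if REF[0] != "T" else "G" * 88
        profile = build_profile([REF, junk], REF)
        assert profile.n_unalignable == 1
        assert profile.n_records == 1

    def test_reverse_strand_records_profiled_in_reference_coordinates(self):
        query = _sub(REF, 30, "A" if REF[30] != "A" else "C")
        rec = ConsensusRecord(sequence=revcomp(query), scheme=1, strand="reverse", support=1)
        profile = build_profile([rec], REF)
        assert profile.counts[31].sum() == 1

    def test_uniform_errors_split_one_to_two_transition_transversion(self):
        # uniform choice over 3 alternates: 1 transition, 2 transversions per base
        e, n_reads = 5e-3, 10_000
        pairs, _ = make_pairs(
            n_molecules=n_reads, copies=CopiesModel.fixed(1),
            sub_rate_fwd=e, seed=29,
        )
        profile = build_profile(
            [p.fwd.payload for p in pairs], REF, scheme="1", strand="forward"
        )
        observed = profile.overall_rate(["transition", "transversion"], start=3, end=86)
        n_nt = int(profile.coverage[3:87].sum())
        sigma = np.sqrt(e * (1 - e) / n_nt)
        assert observed == pytest.approx(e, abs=3 * sigma)
        n_ti = profile.counts[3:87, 0].sum()
        n_tv = profile.counts[3:87, 1].sum()
        p_ti = n_ti / (n_ti + n_tv)
        sigma_ti = np.sqrt((1 / 3) * (2 / 3) / (n_ti + n_tv))
        assert p_ti == pytest.approx(1 / 3, abs=3 * sigma_ti)

    def test_tidy_export_roundtrips_counts(self, tmp_path):
        profile = build_profile([_sub(REF, 10, "A" if REF[10] != "A" else "C")], REF,
                                scheme="1", strand="forward", replicate="replicate1")
        frame = profile.to_frame()
        assert set(frame.columns) == {
            "scheme", "strand", "replicate", "position", "type", "count", "coverage", "rate"
        }
        assert frame["count"].sum() == profile.counts.sum()


class TestTagErrorProbability:
    def test_closed_form_values(self):
        assert tag_error_probability(0.0) == 0.0
        assert tag_error_probability(0.001, 16) == pytest.approx(1 - 0.999**16)
        assert tag_error_probability(0.01, 16) == pytest.approx(0.148542, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tag_error_probability(1.5)
        with pytest.raises(ValueError):
            tag_error_probability(0.1, 0)
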