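import numpy as np
import pytest

from csiscan.alignment_io import CladePartition, ProteinAlignment
from csiscan.detection import (
    DetectionParams,
    IndelCandidate,
    assess_flanks,
    classify_specificity,
    detect_csis,
    extract_query_region,
    find_indel_candidates,
    infer_polarity,
    map_to_reference_coords,
    profile_columns,
)
from conftest import random_alignment
from _oracles import (
    column_tally,
    enumerate_indel_intervals,
    flank_counts,
    map_indel_to_reference,
    score_all_clade_sides,
)


def make_aln(rows: dict[str, str], aln_id="p1") -> ProteinAlignment:
    return ProteinAlignment(id=aln_id, taxa=list(rows), rows=dict(rows))


def gapped_alignment(taxa, length, gap_spec, fill="A"):
    """Alignment of identical sequences with gaps at gap_spec[taxon] = list of
    (start, end) column intervals."""
    rows = {}
    for t in taxa:
        chars = [fill] * length
        for lo, hi in gap_spec.get(t, []):
            for j in range(lo, hi):
                chars[j] = "-"
        rows[t] = "".join(chars)
    return make_aln(rows)


class TestProfileColumns:
    def test_unanimous_column_is_conserved(self):
        aln = make_aln({f"t{i}": "A" * 3 for i in range(10)})
        prof = profile_columns(aln, DetectionParams())
        assert all(p.conserved and p.majority_fraction == 1.0 for p in prof)

    def test_seven_of_ten_below_point_eight_threshold(self):
        rows = {f"t{i}": "A" for i in range(7)}
        rows.update({f"s{i}": "S" for i in range(3)})
        prof = profile_columns(make_aln(rows), DetectionParams())
        assert prof[0].majority_fraction == pytest.approx(0.7)
        assert not prof[0].conserved

    def test_x_excluded_from_majority(self):
        # 4 A + 1 X: majority over informative rows is 4/4, but X never wins
        rows = {"a": "A", "b": "A", "c": "A", "d": "A", "e": "X"}
        prof = profile_columns(make_aln(rows), DetectionParams())
        assert prof[0].majority_residue == "A"
        assert prof[0].majority_fraction == 1.0

    def test_matches_counting_oracle_on_random_alignments(self, rng):
        params = DetectionParams()
        for _ in range(50):
            aln = random_alignment(rng, int(rng.integers(3, 9)),
                                   int(rng.integers(5, 60)))
            got = profile_columns(aln, params)
            want = column_tally(aln, params.conservation_threshold,
                                params.max_column_gap_fraction)
            for p, (res, frac, gapf, cons) in zip(got, want):
                assert p.majority_residue == res
                assert p.majority_fraction == pytest.approx(frac)
                assert p.gap_fraction == pytest.approx(gapf)
                assert p.conserved == cons


class TestFindIndelCandidates:
    def test_ungapped_alignment_yields_nothing(self):
        aln = make_aln({"a": "ACDEF", "b": "ACDEF"})
        assert find_indel_candidates(aln) == []

    def test_shared_two_column_gap(self):
        taxa = ["t1", "t2", "t3", "t4"]
        aln = gapped_alignment(taxa, 20, {"t3": [(10, 12)], "t4": [(10, 12)]})
        (cand,) = find_indel_candidates(aln)
        assert (cand.start, cand.end, cand.length) == (10, 12, 2)
        assert cand.gap_taxa == {"t3", "t4"}
        assert cand.residue_taxa == {"t1", "t2"}

    def test_ragged_run_splits_into_multiple_candidates(self):
        taxa = ["t1", "t2", "t3"]
        aln = gapped_alignment(taxa, 12, {"t2": [(4, 8)], "t3": [(4, 6)]})
        cands = find_indel_candidates(aln)
        assert [(c.start, c.end, set(c.gap_taxa)) for c in cands] == [
            (4, 6, {"t2", "t3"}), (6, 8, {"t2"})]

    def test_equals_exhaustive_enumeration(self, rng):
        for _ in range(60):
            aln = random_alignment(rng, int(rng.integers(2, 9)),
                                   int(rng.integers(5, 121)),
                                   gap_prob=float(rng.uniform(0.05, 0.35)))
            got = [(c.start, c.end, set(c.gap_taxa))
                   for c in find_indel_candidates(aln)]
            want = [(s, e, set(g)) for s, e, g in enumerate_indel_intervals(aln)]
            assert got == want


class TestAssessFlanks:
    def test_three_conserved_left_fails_minimum_five(self):
        # left flank: only 3 identical columns; right flank: plenty
        taxa = [f"t{i}" for i in range(6)]
        n = 60
        rows = {}
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for i, t in enumerate(taxa):
            chars = []
            for j in range(n):
                if j < 17:  # scrambled region: every row different
                    chars.append(residues[(i + j) % 20])
                else:
                    chars.append("A")
            rows[t] = "".join(chars)
        aln = make_aln(rows)
        # punch the indel at columns 20-21 for half the taxa
        for t in taxa[:3]:
            aln.rows[t] = aln.rows[t][:20] + "--" + aln.rows[t][22:]
        params = DetectionParams()
        profiles = profile_columns(aln, params)
        (cand,) = find_indel_candidates(aln)
        fa = assess_flanks(cand, profiles, params)
        assert fa.left_conserved == 3
        assert not fa.passed

    def test_fully_conserved_context_passes(self):
        taxa = [f"t{i}" for i in range(6)]
        aln = gapped_alignment(taxa, 40, {t: [(18, 19)] for t in taxa[:3]})
        params = DetectionParams()
        fa = assess_flanks(find_indel_candidates(aln)[0],
                           profile_columns(aln, params), params)
        assert fa.passed

    def test_counts_match_window_tally_oracle(self, rng):
        params = DetectionParams(flank_window=10, min_conserved_flank=2)
        for _ in range(50):
            aln = random_alignment(rng, int(rng.integers(3, 8)),
                                   int(rng.integers(20, 100)))
            profiles = profile_columns(aln, params)
            for cand in find_indel_candidates(aln)[:5]:
                fa = assess_flanks(cand, profiles, params)
                left, right = flank_counts(aln, cand.start, cand.end, params)
                assert (fa.left_conserved, fa.right_conserved) == (left, right)


def _candidate(gap_taxa, all_taxa, aln_id="p1"):
    return IndelCandidate(protein_id=aln_id, start=10, end=12,
                          gap_taxa=frozenset(gap_taxa),
                          residue_taxa=frozenset(set(all_taxa) - set(gap_taxa)))


class TestClassifySpecificity:
    def test_two_member_clade_with_lowered_min_carriers(self, glires_partition):
        taxa = sorted(glires_partition.taxa)
        castor = {"Dipodomys_ordii", "Dipodomys_spectabilis"}
        cand = _candidate(castor, taxa)
        params = DetectionParams(min_carriers=2, max_exceptions=1)
        a = classify_specificity(cand, glires_partition, params)
        assert a is not None and a.label == "Castorimorpha"
        assert a.exceptions == {"Castor_canadensis"}

    def test_two_taxa_from_different_suborders_rejected(self, glires_partition):
        taxa = sorted(glires_partition.taxa)
        cand = _candidate({"Mus_musculus", "Cavia_porcellus"}, taxa)
        assert classify_specificity(cand, glires_partition,
                                    DetectionParams(min_carriers=2)) is None

    def test_exact_clade_assignment(self, glires_partition):
        taxa = sorted(glires_partition.taxa)
        hystrico = glires_partition.members("suborder", "Hystricomorpha")
        cand = _candidate(hystrico, taxa)
        a = classify_specificity(cand, glires_partition, DetectionParams())
        assert (a.level, a.label) == ("suborder", "Hystricomorpha")
        assert a.carriers == hystrico and not a.exceptions

    def test_foreign_carrier_defeats_exclusivity(self, glires_partition):
        taxa = sorted(glires_partition.taxa)
        side = glires_partition.members("suborder", "Hystricomorpha") | \
            {"Mus_musculus"}
        cand = _candidate(side, taxa)
        assert classify_specificity(cand, glires_partition,
                                    DetectionParams()) is None

    def test_agrees_with_exhaustive_scoring(self, toy_partition, rng):
        taxa = sorted(toy_partition.taxa)
        params = DetectionParams(min_carriers=2)
        for _ in range(60):
            k = int(rng.integers(1, len(taxa)))
            side = set(rng.choice(taxa, size=k, replace=False))
            cand = _candidate(side, taxa)
            got = classify_specificity(cand, toy_partition, params)
            want = score_all_clade_sides(set(cand.gap_taxa),
                                         set(cand.residue_taxa),
                                         toy_partition, params)
            if not want:
                assert got is None
                continue
            smallest = want[0][0]
            tied = {(lv, lb) for sz, lv, lb, _ in want if sz == smallest}
            if len(tied) > 1:
                assert got is None
            else:
                assert (got.level, got.label) in tied


class TestInferPolarity:
    def test_extra_residues_in_carriers_is_insertion(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        carriers = frozenset({"a0", "a1", "a2", "a3"})
        cand = _candidate(set(taxa) - carriers, taxa)  # others gapped
        assert infer_polarity(cand, toy_partition, carriers) == "insertion"

    def test_gapped_carriers_with_residue_outgroups_is_deletion(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        carriers = frozenset({"a0", "a1", "a2", "a3"})
        cand = _candidate(carriers, taxa)
        assert infer_polarity(cand, toy_partition, carriers) == "deletion"

    def test_swapping_gap_states_flips_polarity(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        carriers = frozenset({"b0", "b1", "b2", "b3"})
        ins = _candidate(set(taxa) - carriers, taxa)
        dele = _candidate(carriers, taxa)
        assert infer_polarity(ins, toy_partition, carriers) == "insertion"
        assert infer_polarity(dele, toy_partition, carriers) == "deletion"

    def test_mixed_outgroups_undetermined(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        carriers = frozenset({"a0", "a1", "a2", "a3"})
        cand = _candidate(carriers | {"og1"}, taxa)  # one outgroup gapped too
        assert infer_polarity(cand, toy_partition, carriers) == "undetermined"

    def test_no_outgroup_logs_and_returns_undetermined(self, caplog):
        part = CladePartition(
            taxa={"a", "b", "c", "d"},
            levels={"g": {"a": "A", "b": "A"}},
            outgroups=set(),
            candidate_clades=[("g", "A")])
        cand = _candidate({"a", "b"}, ["a", "b", "c", "d"])
        assert infer_polarity(cand, part, frozenset({"a", "b"})) == "undetermined"


class TestReferenceCoordinates:
    def _call(self, aln, partition, **kw):
        params = kw.pop("params", DetectionParams(min_carriers=2, **kw))
        calls = detect_csis(aln, partition, params)
        assert calls, "expected a detected CSI"
        return calls[0], params

    def test_single_column_indel_maps_to_eleven_plus_minus_five(self, toy_partition):
        # indel at column interval [10, 11); reference ungapped: the indel is
        # residue 11, displayed with 5 conserved columns per side -> [6, 16]
        taxa = sorted(toy_partition.taxa)
        aln = gapped_alignment(taxa, 120, {t: [(10, 11)]
                                           for t in ("a0", "a1", "a2", "a3")})
        call, params = self._call(aln, toy_partition)
        assert call.reference_taxon in call.candidate.residue_taxa
        got = map_to_reference_coords(call, aln, call.reference_taxon,
                                      params=params)
        assert got == (6, 16)

    def test_leading_reference_gaps_do_not_shift_positions(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        gap_spec = {t: [(10, 11)] for t in ("a0", "a1", "a2", "a3")}
        aln = gapped_alignment(taxa, 120, gap_spec)
        ref = "b0"
        # prepend 3 gap columns to the reference only (others get residues)
        rows = {t: ("NNN" if t != ref else "---") + aln.rows[t]
                for t in taxa}
        aln2 = ProteinAlignment(id="p1", taxa=taxa, rows=rows)
        params = DetectionParams(min_carriers=2)
        call1 = detect_csis(aln, toy_partition, params)[0]
        call2 = detect_csis(aln2, toy_partition, params)[0]
        assert map_to_reference_coords(call1, aln, ref, params=params) == \
            map_to_reference_coords(call2, aln2, ref, params=params)

    def test_matches_gap_aware_mapping_oracle(self, toy_partition, rng):
        taxa = sorted(toy_partition.taxa)
        params = DetectionParams(min_carriers=2)
        checked = 0
        while checked < 50:
            aln = random_alignment(rng, 6, 100, gap_prob=0.1)
            cands = find_indel_candidates(aln)
            if not cands:
                continue
            part = CladePartition(
                taxa=set(aln.taxa), levels={"g": {}}, outgroups=set(),
                candidate_clades=[])
            for cand in cands[:3]:
                ref = sorted(cand.residue_taxa)[0]
                from csiscan.detection import CSICall, FlankAssessment
                call = CSICall(protein_id=aln.id, candidate=cand,
                               clade_level="g", clade_label="x",
                               carriers=cand.gap_taxa, exceptions=frozenset(),
                               foreign=frozenset(), polarity="undetermined",
                               flanks=FlankAssessment(0, 0, False))
                got = map_to_reference_coords(call, aln, ref, params=params)
                want = map_indel_to_reference(aln, ref, cand.start, cand.end,
                                              params)
                assert got == want
                checked += 1

    def test_query_region_spans_flank_and_clips(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        aln = gapped_alignment(taxa, 300, {t: [(99, 101)]
                                           for t in ("a0", "a1", "a2", "a3")})
        call, params = self._call(aln, toy_partition)
        ref = "b0"  # ungapped reference: indel is residues 100-101
        region = extract_query_region(call, aln, ref, flank_aa=60)
        # residues 40..161 inclusive
        assert len(region) == 122
        degapped = aln.rows[ref].replace("-", "")
        assert region == degapped[39:161]
        # an indel near the start clips at residue 1
        aln2 = gapped_alignment(taxa, 300, {t: [(9, 11)]
                                            for t in ("a0", "a1", "a2", "a3")})
        call2 = detect_csis(aln2, toy_partition,
                            DetectionParams(min_carriers=2))[0]
        region2 = extract_query_region(call2, aln2, ref, flank_aa=60)
        assert region2 == aln2.rows[ref].replace("-", "")[:71]


class TestDetectCsis:
    def test_ungapped_alignment_gives_no_calls(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        aln = gapped_alignment(taxa, 100, {})
        assert detect_csis(aln, toy_partition) == []

    def test_clean_clade_deletion_called_once(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        aln = gapped_alignment(taxa, 120, {t: [(50, 53)]
                                           for t in ("a0", "a1", "a2", "a3")})
        calls = detect_csis(aln, toy_partition)
        assert len(calls) == 1
        c = calls[0]
        assert (c.clade_label, c.length, c.polarity) == ("A", 3, "deletion")
        assert c.carriers == {"a0", "a1", "a2", "a3"}

    def test_ragged_lengths_yield_zero_calls(self, toy_partition):
        # same start, lengths 2/3/3/4: violates the fixed-length rule
        taxa = sorted(toy_partition.taxa)
        aln = gapped_alignment(taxa, 120, {
            "a0": [(50, 52)], "a1": [(50, 53)], "a2": [(50, 53)],
            "a3": [(50, 54)]})
        assert detect_csis(aln, toy_partition) == []

    def test_row_permutation_invariance(self, toy_partition, rng):
        taxa = sorted(toy_partition.taxa)
        aln = gapped_alignment(taxa, 120, {t: [(30, 32)]
                                           for t in ("b0", "b1", "b2", "b3")})
        shuffled = list(taxa)
        rng.shuffle(shuffled)
        aln2 = ProteinAlignment(id="p1", taxa=shuffled,
                                rows={t: aln.rows[t] for t in shuffled})
        c1 = detect_csis(aln, toy_partition)
        c2 = detect_csis(aln2, toy_partition)
        assert [(c.candidate.start, c.candidate.end, c.clade_label,
                 c.polarity, set(c.carriers)) for c in c1] == \
            [(c.candidate.start, c.candidate.end, c.clade_label,
              c.polarity, set(c.carriers)) for c in c2]

    def test_appending_conserved_block_changes_nothing(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        aln = gapped_alignment(taxa, 120, {t: [(60, 61)]
                                           for t in ("a0", "a1", "a2", "a3")})
        aln2 = ProteinAlignment(
            id="p1", taxa=taxa,
            rows={t: "WWWWW" + aln.rows[t] + "YYYYY" for t in taxa})
        c1 = detect_csis(aln, toy_partition)
        c2 = detect_csis(aln2, toy_partition)
        assert len(c1) == len(c2) == 1
        assert c2[0].candidate.start == c1[0].candidate.start + 5
        assert c1[0].clade_label == c2[0].clade_label
        assert c1[0].polarity == c2[0].polarity

    def test_reported_length_equals_interval_length(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        for ln in (1, 2, 5):
            aln = gapped_alignment(taxa, 150, {t: [(70, 70 + ln)]
                                               for t in ("a0", "a1", "a2", "a3")})
            (c,) = detect_csis(aln, toy_partition)
            assert c.length == ln == c.candidate.end - c.candidate.start

    def test_raising_max_exceptions_is_monotone(self, toy_partition):
        taxa = sorted(toy_partition.taxa)
        # a3 lacks the deletion: one exception needed
        aln = gapped_alignment(taxa, 120, {t: [(50, 52)]
                                           for t in ("a0", "a1", "a2")})
        found = {}
        for k in (0, 1, 2):
            calls = detect_csis(aln, toy_partition,
                                DetectionParams(max_exceptions=k))
            found[k] = {(c.candidate.start, c.clade_label) for c in calls}
        assert found[0] <= found[1] <= found[2]
        assert found[1], "one exception should allow the call"
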