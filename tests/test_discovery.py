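import numpy as np
import pytest

from mosaicsv.config import PipelineConfig
from mosaicsv.discovery import (BreakpointCandidate, InsertStats, SvCall,
                                call_somatic_pairwise, cluster_breakpoints,
                                estimate_insert_stats, extract_abnormal_reads,
                                filter_known_germline, flag_mda_artifacts,
                                group_adjacent_complex, merge_reciprocal,
                                pair_and_type, read_bed)
from mosaicsv.genome import build_reference, revcomp
from mosaicsv.simulate import AlignmentRecord

CFG = PipelineConfig()
STATS = InsertStats(mean=400.0, sd=50.0)


def _read(contig="chr1", pos=1000, clip_left=0, clip_right=0, insert=400,
          mate_contig=None, proper=True, sample="s", seq=None, read_id="r"):
    alen = 150 - clip_left - clip_right
    return AlignmentRecord(
        sample_id=sample, read_id=read_id, contig=contig, pos=pos, strand="+",
        aligned_len=alen, clip_left=clip_left, clip_right=clip_right,
        sequence=seq or "A" * 150, mate_contig=mate_contig or contig,
        mate_pos=pos + 250, insert_size=insert, is_proper_pair=proper)


class TestAbnormalReads:
    def test_soft_clip_boundary_is_strictly_greater_than_30(self):
        clipped31 = _read(clip_right=31, proper=False)
        clipped30 = _read(clip_right=30, proper=False)
        out = extract_abnormal_reads([clipped31, clipped30], config=CFG,
                                     insert_stats=STATS)
        assert out == [clipped31]

    def test_normal_insert_proper_pair_not_abnormal(self):
        assert extract_abnormal_reads([_read(insert=400)], config=CFG,
                                      insert_stats=STATS) == []

    def test_discordant_insert_cutoff_is_mean_plus_3_sd(self):
        over = _read(insert=551)
        under = _read(insert=549)
        out = extract_abnormal_reads([over, under], config=CFG,
                                     insert_stats=STATS)
        assert out == [over]

    def test_inter_contig_mate_is_abnormal(self):
        r = _read(mate_contig="chr2")
        assert extract_abnormal_reads([r], config=CFG, insert_stats=STATS) == [r]

    def test_locus_restriction(self):
        near = _read(pos=5_100, clip_right=40)
        far = _read(pos=20_000, clip_right=40)
        out = extract_abnormal_reads([near, far], locus=("chr1", 5_000, 6_000),
                                     config=CFG, insert_stats=STATS)
        assert out == [near]

    def test_insert_estimation_requires_enough_pairs(self):
        with pytest.raises(ValueError):
            estimate_insert_stats([_read() for _ in range(10)])


class TestClustering:
    def test_identical_positions_form_one_candidate(self):
        reads = [_read(pos=1000, clip_right=40, proper=False, read_id=f"r{i}")
                 for i in range(5)]
        cands = cluster_breakpoints(reads, CFG)
        assert len(cands) == 1
        assert cands[0].split_support == 5
        assert cands[0].pos == 1000 + 110  # clip at the aligned end

    def test_tolerance_splits_distant_clusters(self):
        a = [_read(pos=p, clip_right=40, proper=False, read_id=f"a{i}")
             for i, p in enumerate([100, 103, 100])]
        b = [_read(pos=2000, clip_right=40, proper=False, read_id=f"b{i}")
             for i in range(3)]
        cands = cluster_breakpoints(a + b, CFG)
        assert len(cands) == 2

    def test_min_split_support_threshold(self):
        reads = [_read(pos=1000, clip_right=40, proper=False, read_id=f"r{i}")
                 for i in range(2)]
        assert cluster_breakpoints(reads, CFG) == []


def _cand(ref, contig, pos, side, seq):
    return BreakpointCandidate(contig=contig, pos=pos, side=side,
                               split_support=5, clip_consensus=seq)


class TestTyping:
    @pytest.fixture()
    def ref(self, plain_ref):
        return plain_ref

    def test_canonical_deletion_signature(self, ref):
        a, b = 5_000, 6_000
        s = ref.contigs["chr1"]
        A = _cand(ref, "chr1", a, "right", s[b:b + 60])
        B = _cand(ref, "chr1", b, "left", s[a - 60:a])
        calls = pair_and_type([A, B], ref, "s", CFG)
        assert [c.sv_type for c in calls] == ["DEL"]
        assert (calls[0].start, calls[0].end) == (a, b)

    def test_tandem_duplication_signature(self, ref):
        a, b = 5_000, 6_000
        s = ref.contigs["chr1"]
        A = _cand(ref, "chr1", a, "left", s[b - 60:b])
        B = _cand(ref, "chr1", b, "right", s[a:a + 60])
        calls = pair_and_type([A, B], ref, "s", CFG)
        assert [c.sv_type for c in calls] == ["DUP"]

    def test_inversion_signature_right_right(self, ref):
        a, b = 5_000, 6_000
        s = ref.contigs["chr1"]
        A = _cand(ref, "chr1", a, "right", revcomp(s[b - 60:b]))
        B = _cand(ref, "chr1", b, "right", revcomp(s[a - 60:a]))
        calls = pair_and_type([A, B], ref, "s", CFG)
        assert [c.sv_type for c in calls] == ["INV"]

    def test_intercontig_pair_is_bnd(self, ref):
        A = _cand(ref, "chr1", 5_000, "right", ref.contigs["chr2"][7_000:7_060])
        B = _cand(ref, "chr2", 7_000, "left", ref.contigs["chr1"][4_940:5_000])
        calls = pair_and_type([A, B], ref, "s", CFG)
        assert [c.sv_type for c in calls] == ["BND"]
        assert not calls[0].one_sided

    def test_unmatched_inverted_candidate_is_one_sided_bnd(self, ref):
        s = ref.contigs["chr1"]
        A = _cand(ref, "chr1", 5_000, "right", revcomp(s[4_840:4_900]))
        calls = pair_and_type([A], ref, "s", CFG)
        assert calls[0].sv_type == "BND" and calls[0].one_sided
        assert calls[0].inverted

    def test_one_sided_deletion_rescue(self, ref):
        # only the donor-side cluster reached support: the clipped sequence
        # locates the partner and the call is still typed DEL
        s = ref.contigs["chr1"]
        A = _cand(ref, "chr1", 5_000, "right", s[6_000:6_060])
        calls = pair_and_type([A], ref, "s", CFG)
        assert calls[0].sv_type == "DEL"
        assert (calls[0].start, calls[0].end) == (5_000, 6_000)


def _call(sample="A", sv_type="DEL", contig="chr1", start=1000, end=2000):
    return SvCall(sv_type, sample, contig, start, end,
                  [(contig, start, "right"), (contig, end, "left")],
                  split_support=5)


class TestSomaticVoting:
    def test_private_sv_gets_all_votes(self):
        call = _call("A")
        controls = {f"ctrl{i}": [] for i in range(9)}
        call_somatic_pairwise([call], controls, CFG)
        assert call.comparison_votes == 9

    def test_germline_sv_gets_no_votes(self):
        call = _call("A")
        support = [_read(pos=890, clip_right=40, proper=False)]
        controls = {f"ctrl{i}": support for i in range(9)}
        call_somatic_pairwise([call], controls, CFG)
        assert call.comparison_votes == 0

    def test_two_carrier_sv_votes_against_non_carriers_only(self):
        # 10 clones, carriers A and B: each carrier wins 8 of 9 comparisons
        support = [_read(pos=890, clip_right=40, proper=False)]
        clones = {f"c{i}": [] for i in range(8)}
        clones["A"] = support
        clones["B"] = support
        from mosaicsv.discovery import recurrence_filter
        calls_by = {}
        for carrier in ("A", "B"):
            call = _call(carrier)
            call_somatic_pairwise([call], {k: v for k, v in clones.items()
                                           if k != carrier}, CFG)
            assert call.comparison_votes == 8
            assert call.informative_comparisons == 9
            calls_by[carrier] = [call]
        kept = recurrence_filter(calls_by, CFG)
        assert len(kept) == 1
        assert kept[0].carriers == ["A", "B"]

    def test_symmetry_no_locus_votes_somatic_both_ways(self):
        support = [_read(pos=890, clip_right=40, proper=False)]
        a_call, b_call = _call("A"), _call("B")
        call_somatic_pairwise([a_call], {"B": support}, CFG)
        call_somatic_pairwise([b_call], {"A": support}, CFG)
        assert a_call.comparison_votes == 0 and b_call.comparison_votes == 0


class TestRecurrence:
    def test_full_votes_retained_low_votes_removed(self):
        from mosaicsv.discovery import recurrence_filter
        keep = _call("A")
        keep.comparison_votes, keep.informative_comparisons = 9, 9
        drop = _call("B", start=9000, end=9900)
        drop.comparison_votes, drop.informative_comparisons = 3, 9
        kept = recurrence_filter({"A": [keep], "B": [drop]}, CFG)
        assert kept == [keep]


class TestMergeAndGroup:
    def test_reciprocal_overlap_boundary(self):
        a = _call(start=100, end=200)
        b = _call(start=150, end=250)      # overlap 50 = 0.5 x 100: merged
        merged = merge_reciprocal([a, b], CFG)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 250)

    def test_insufficient_overlap_kept_separate(self):
        a = _call(start=100, end=200)
        b = _call(start=190, end=400)      # 10/300 < 0.5
        assert len(merge_reciprocal([a, b], CFG)) == 2

    def test_identical_spans_merge_and_idempotence(self):
        rng = np.random.default_rng(0)
        calls = [_call(start=int(s), end=int(s) + int(l))
                 for s, l in zip(rng.integers(0, 5000, 30),
                                 rng.integers(50, 500, 30))]
        once = merge_reciprocal(calls, CFG)
        spans1 = sorted((c.start, c.end) for c in once)
        twice = merge_reciprocal(once, CFG)
        assert sorted((c.start, c.end) for c in twice) == spans1

    def test_adjacency_grouping_is_a_partition(self):
        near1 = _call(start=4_000, end=5_000)
        near2 = _call(sv_type="INV", start=5_400, end=5_900)   # 400 < 1000
        far = _call(start=20_000, end=21_000)
        groups = group_adjacent_complex([near1, near2, far], CFG)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 2]
        assert sum(sizes) == 3      # every call in exactly one group


class TestArtifactAndCatalog:
    def test_mda_pattern_flagged(self):
        bnd = SvCall("BND", "s", "chr1", 5_000, 5_000,
                     [("chr1", 5_000, "right")], 5, inverted=True,
                     one_sided=True)
        dup = _call(sv_type="DUP", start=5_400, end=5_700)
        flags = flag_mda_artifacts([[bnd, dup]], CFG)
        assert flags == [True]

    def test_reciprocal_del_dup_not_flagged(self):
        d = _call(sv_type="DEL", start=5_000, end=6_000)
        u = _call(sv_type="DUP", start=5_000, end=6_000)
        assert flag_mda_artifacts([[d, u]], CFG) == [False]

    def test_simple_deletion_not_flagged(self):
        assert flag_mda_artifacts([[_call()]], CFG) == [False]

    def test_catalog_filter(self):
        call = _call(start=100, end=200)
        assert filter_known_germline([call], [("chr1", 100, 200)], CFG) == []
        assert filter_known_germline([call], [], CFG) == [call]
        # 10% reciprocal overlap: retained
        kept = filter_known_germline([call], [("chr1", 190, 1100)], CFG)
        assert kept == [call]
        with pytest.raises(ValueError):
            filter_known_germline([call], [("chr1", 200, 100)], CFG)

    def test_malformed_bed_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError):
            read_bed(p)
        p2 = tmp_path / "ok.bed"
        p2.write_text("# comment\nchr1\t100\t200\tname\n")
        assert read_bed(p2) == [("chr1", 100, 200)]
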