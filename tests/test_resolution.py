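import numpy as np
import pytest

from mosaicsv.alleles import AltAlleleSpec, implant_sv
from mosaicsv.assembly import KmerIndex, SegmentAlignment
from mosaicsv.config import PipelineConfig
from mosaicsv.discovery import SvCall
from mosaicsv.genome import Segment, build_reference, revcomp
from mosaicsv.rearrangement import (count_template_switches, detect_microhomology,
                                    events_from_chain, model_from_chain,
                                    size_spectra)
from mosaicsv.resolve import (classify_rearrangement, detect_eccdna,
                              explanation_score, passes_explanation,
                              resolve_contig)
from mosaicsv.simulate import AlignmentRecord

CFG = PipelineConfig()


class TestClassification:
    def test_collinear_chain_has_no_events_or_switches(self, plain_ref):
        aln = SegmentAlignment(0, 400, Segment("chr1", 5_000, 5_400), 1.0)
        model = classify_rearrangement([aln], plain_ref)
        assert model.events == [] and model.template_switches == 0

    def test_two_deletions_one_inversion_one_duplication_is_four_switches(self):
        """The canonical complex allele: a chain whose coverage arithmetic
        yields DEL+DEL+DUP+INV requires exactly four replication-fork
        template switches."""
        anchor = ("chr1", 10_000, 12_000)
        chain = [Segment("chr1", 10_350, 11_000),             # DEL in front
                 Segment("chr1", 10_600, 10_950, "reverse"),  # INV + DUP
                 Segment("chr1", 11_000, 11_600)]             # DEL at the end
        events, _region, _part = events_from_chain(*anchor, chain)
        kinds = sorted(e.kind for e in events)
        assert kinds == ["DEL", "DEL", "DUP", "INV"]
        switches, jumps = count_template_switches(*anchor, chain)
        assert switches == 4
        assert len(jumps) == 4

    def test_interchromosomal_chain_model(self, small_ref):
        spec = AltAlleleSpec(
            anchor=("chr1", 5_000), deleted_span=13,
            chain=[Segment("chr1", 25_000, 25_159, "reverse"),
                   Segment("chr2", 7_000, 7_140),
                   Segment("chr2", 20_000, 20_159)],
            junction_mh=[2, 3, 4, 2], label="x")
        _alt, truth = implant_sv(small_ref, spec)
        model = model_from_chain("chr1", 5_000, 5_013, spec.chain,
                                 junction_mh=spec.junction_mh)
        assert model.event_multiset == truth.event_multiset
        assert model.absolute_size == 445
        assert model.template_switches == 4
        # inter-chromosomal jumps are recorded as None
        assert model.switch_distances.count(None) == 2

    def test_unanchored_chain_requires_explicit_region(self, plain_ref):
        alns = [SegmentAlignment(0, 100, Segment("chr1", 5_000, 5_100, "reverse"), 1.0),
                SegmentAlignment(100, 200, Segment("chr2", 7_000, 7_100), 1.0)]
        with pytest.raises(ValueError):
            classify_rearrangement(alns, plain_ref)


class TestMicrohomology:
    def test_shared_three_base_suffix(self):
        # donor ends ...GAT and the acceptor's preceding bases end ...GAT
        assert detect_microhomology("AACTGAT", "TTACG", "CCCAGAT", "GGACT") == 3

    def test_no_shared_bases(self):
        assert detect_microhomology("AAAA", "CCCC", "GGGG", "TTTT") == 0

    def test_maximum_of_left_and_right_conventions(self):
        # right homology 2 (donor continuation CC == acceptor start CC),
        # left homology 0
        assert detect_microhomology("AAAT", "CCGG", "TTTG", "CCAA") == 2

    def test_truncated_flanks_cap_the_measurement(self):
        assert detect_microhomology("AT", "C", "AT", "G", max_mh=20) == 2


class TestSpectraAndConservation:
    def test_single_deletion_spectrum(self):
        model = model_from_chain("chr1", 1_000, 1_500, [], junction_mh=[0])
        df = size_spectra([model])
        assert df[df.kind == "deleted_region"]["size"].tolist() == [500]
        assert df[df.kind == "replicated_fragment"].empty

    def test_deletion_with_adjacent_inversion_spectrum(self):
        """A large deleted region with an adjacent inverted fragment keeps
        both sizes in the spectra (1891-bp deletion, 243-bp inversion)."""
        chain = [Segment("chr1", 11_891, 12_134, "reverse")]
        model = model_from_chain("chr1", 10_000, 12_134, chain,
                                 junction_mh=[2, 2])
        assert model.deleted_region_sizes == [1891]
        assert 243 in model.replicated_fragment_sizes
        df = size_spectra([model])
        assert set(df.kind) == {"switch", "replicated_fragment", "deleted_region"}

    def test_partition_identity_holds_on_random_chains(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            anchor_start = 10_000
            anchor_end = anchor_start + int(rng.integers(0, 2_000))
            chain = []
            for _k in range(int(rng.integers(0, 4))):
                s = int(rng.integers(5_000, 25_000))
                e = s + int(rng.integers(50, 1_500))
                chain.append(Segment("chr1", s, e,
                                     "reverse" if rng.random() < 0.5 else "forward"))
            _ev, (c, r0, r1), part = events_from_chain(
                "chr1", anchor_start, anchor_end, chain)
            assert part["deleted"] + part["replicated"] + part["collinear"] \
                == r1 - r0


class TestExplanationScore:
    def _reads(self, target, n_ok, n_bad):
        good = [AlignmentRecord("s", f"g{i}", "chr1", 0, "+", 150, 0, 0,
                                target[i * 3: i * 3 + 120])
                for i in range(n_ok)]
        bad = [AlignmentRecord("s", f"b{i}", "chr1", 0, "+", 150, 0, 0,
                               "ACGT" * 30) for i in range(n_bad)]
        return good + bad

    def test_all_reads_consistent_scores_one(self, plain_ref):
        model = model_from_chain("chr1", 5_000, 5_100, [], junction_mh=[0])
        model.contig_sequence = plain_ref.contigs["chr1"][4_000:6_000]
        reads = self._reads(model.contig_sequence, 20, 0)
        score = explanation_score(model, reads, CFG)
        assert score == 1.0 and passes_explanation(score, CFG)

    def test_exactly_point_eight_is_rejected(self, plain_ref):
        model = model_from_chain("chr1", 5_000, 5_100, [], junction_mh=[0])
        model.contig_sequence = plain_ref.contigs["chr1"][4_000:6_000]
        reads = self._reads(model.contig_sequence, 16, 4)
        score = explanation_score(model, reads, CFG)
        assert score == pytest.approx(0.8)
        assert not passes_explanation(score, CFG)   # strictly-greater rule

    def test_zero_consistent_reads(self, plain_ref):
        model = model_from_chain("chr1", 5_000, 5_100, [], junction_mh=[0])
        model.contig_sequence = plain_ref.contigs["chr1"][4_000:6_000]
        assert explanation_score(model, self._reads("", 0, 10), CFG) == 0.0


class TestEccDna:
    def _call(self, sv_type, start, end):
        return SvCall(sv_type, "s", "chr1", start, end,
                      [("chr1", start, "right"), ("chr1", end, "left")], 5)

    def test_reciprocal_del_dup_fused(self):
        d = self._call("DEL", 5_000, 6_200)
        u = self._call("DUP", 5_000, 6_200)
        events, remaining = detect_eccdna([d, u], CFG)
        assert len(events) == 1 and remaining == []
        assert (events[0].start, events[0].end) == (5_000, 6_200)

    def test_offset_breakpoints_not_fused(self):
        d = self._call("DEL", 5_000, 6_200)
        u = self._call("DUP", 10_000, 11_200)
        events, remaining = detect_eccdna([d, u], CFG)
        assert events == [] and len(remaining) == 2


class TestStrandInvolution:
    def test_reverse_complemented_contig_gives_mirror_model(self):
        ref = build_reference(19, 2, 30_000, snp_density=0)
        spec = AltAlleleSpec(anchor=("chr1", 12_000), deleted_span=600,
                             chain=[Segment("chr1", 20_000, 20_400, "reverse")],
                             junction_mh=[2, 3], label="v")
        implant_sv(ref, spec)
        s = ref.contigs["chr1"]
        contig = s[11_700:12_000] + revcomp(s[20_000:20_400]) + s[12_600:12_900]
        idx = KmerIndex(ref, 15)
        fwd = resolve_contig(contig, ref, index=idx, config=CFG)
        rev = resolve_contig(revcomp(contig), ref, index=idx, config=CFG)
        assert fwd is not None and rev is not None
        assert fwd.event_multiset == rev.event_multiset
        assert fwd.absolute_size == rev.absolute_size
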