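import pandas as pd
import pytest

from mosaicsv.config import PipelineConfig
from mosaicsv.genotyping import (GenotypeResult, af_upper_bound,
                                 build_pseudoreference, call_homozygous_sites,
                                 classify_clonality, cnv_depth_filter,
                                 genotype_all, map_reads_unique)
from mosaicsv.rearrangement import model_from_chain
from mosaicsv.simulate import AlignmentRecord

CFG = PipelineConfig()


def _model(ref, anchor=15_000, deleted=500):
    m = model_from_chain("chr1", anchor, anchor + deleted, [], junction_mh=[0])
    m.contig_sequence = ref.contigs["chr1"][anchor - 200:anchor] \
        + ref.contigs["chr1"][anchor + deleted:anchor + deleted + 200]
    return m


class TestPseudoReference:
    def test_length_is_alt_plus_two_flanks(self, small_ref):
        model = _model(small_ref)
        pseudo = build_pseudoreference(model.contig_sequence, small_ref, model)
        assert len(pseudo.sequence) == 0 + 2 * CFG.flank   # pure deletion ALT
        assert len(pseudo.ref_sequence) == 500 + 2 * CFG.flank

    def test_homozygous_snp_in_flank_reverted_and_logged(self, small_ref):
        model = _model(small_ref)
        pos = 14_000
        ref_base = small_ref.contigs["chr1"][pos]
        alt_base = "A" if ref_base != "A" else "G"
        # pretend the flank carries the hom variant: mutate the genome copy
        mutated = small_ref.copy()
        mutated.contigs["chr1"] = (small_ref.contigs["chr1"][:pos] + alt_base
                                   + small_ref.contigs["chr1"][pos + 1:])
        panel = [("chr1", pos, ref_base, alt_base)]
        pseudo = build_pseudoreference(model.contig_sequence, mutated, model,
                                       snp_panel=panel)
        assert ("chr1", pos) in pseudo.reverted_site_log
        offset = pos - pseudo.left_flank_start
        assert pseudo.sequence[offset] == ref_base

    def test_het_site_not_in_panel_left_untouched(self, small_ref):
        model = _model(small_ref)
        pseudo = build_pseudoreference(model.contig_sequence, small_ref, model,
                                       snp_panel=[])
        assert pseudo.reverted_site_log == []

    def test_empty_contig_rejected(self, small_ref):
        with pytest.raises(ValueError):
            build_pseudoreference("", small_ref, _model(small_ref))

    def test_hom_site_caller_thresholds(self):
        fracs = {("chr1", 10): [0.95, 0.92, 1.0, 0.97],   # hom in all clones
                 ("chr1", 20): [0.95, 0.5, 0.45, 0.5]}    # het-like
        bases = {("chr1", 10): ("A", "T"), ("chr1", 20): ("C", "G")}
        panel = call_homozygous_sites(fracs, bases, CFG)
        assert panel == [("chr1", 10, "A", "T")]


class TestUniqueMapping:
    def test_junction_read_counts_alt_flank_read_counts_neither(self, small_ref):
        model = _model(small_ref, deleted=500)
        pseudo = build_pseudoreference(model.contig_sequence, small_ref, model)
        j = pseudo.alt_diagnostic[0]
        alt_read = AlignmentRecord("s", "a", "chr1", 0, "+", 150, 0, 0,
                                   pseudo.sequence[j - 75:j + 75])
        flank_read = AlignmentRecord("s", "f", "chr1", 0, "+", 150, 0, 0,
                                     pseudo.sequence[100:250])
        ref_read = AlignmentRecord("s", "r", "chr1", 0, "+", 150, 0, 0,
                                   pseudo.ref_sequence[j - 75:j + 75])
        n_alt, n_ref = map_reads_unique([alt_read, flank_read, ref_read],
                                        pseudo, CFG)
        assert (n_alt, n_ref) == (1, 1)


class TestAfUpperBound:
    def test_bound_values(self):
        assert af_upper_bound(167) == pytest.approx(0.5 / 167)
        assert af_upper_bound(167) * 100 == pytest.approx(0.2994, abs=1e-4)
        assert af_upper_bound(1) == 0.5
        assert af_upper_bound(50) == pytest.approx(0.01)

    def test_strictly_decreasing_in_capacity(self):
        bounds = [af_upper_bound(n) for n in range(1, 200)]
        assert all(a > b for a, b in zip(bounds, bounds[1:]))

    def test_no_capacity_rejected(self):
        with pytest.raises(ValueError):
            af_upper_bound(0)


class TestClonality:
    def test_balanced_af_single_haplotype_is_clonal(self):
        g = GenotypeResult("s", 20, 22, 20 / 42, present=True)
        assert classify_clonality(g, [(10, 0), (8, 0)], CFG) == "clonal"

    def test_low_af_is_subclonal(self):
        g = GenotypeResult("s", 3, 37, 3 / 40, present=True)
        assert classify_clonality(g, [], CFG) == "subclonal"

    def test_both_snp_alleles_in_deleted_region_forces_subclonal(self):
        g = GenotypeResult("s", 20, 20, 0.5, present=True)
        assert classify_clonality(g, [(9, 7)], CFG) == "subclonal"


def _profiles(cn_by_sample, contig="chr1", bins=10, bin_size=200):
    rows = []
    for sample, cn in cn_by_sample.items():
        for b in range(bins):
            rows.append((sample, contig, b * bin_size, 40, False, cn))
    return pd.DataFrame(rows, columns=["sample", "contig", "bin_start",
                                       "count", "in_gap", "norm_cn"])


class TestCnvDepthFilter:
    SPAN = ("chr1", 200, 1400)
    OTHERS = [f"o{i}" for i in range(5)]

    def _run(self, tissue, clone, others, sv_type="DEL", gaps=None, cfg=CFG):
        cns = {"tissue": tissue, "clone": clone}
        cns.update({o: cn for o, cn in zip(self.OTHERS, others)})
        return cnv_depth_filter(_profiles(cns), self.SPAN, sv_type, "tissue",
                                "clone", self.OTHERS, gaps=gaps, config=cfg)

    def test_textbook_deletion_passes(self):
        ok, reasons = self._run(2.0, 1.0, [2.0] * 5)
        assert ok, reasons

    @pytest.mark.parametrize("tissue,clone,others,should_pass", [
        (1.6, 1.0, [1.6] * 5, True),     # tissue exactly at the 1.6 floor
        (1.59, 1.0, [2.0] * 5, False),   # tissue below the floor
        (2.0, 1.4, [2.0] * 5, True),     # clone exactly at the 1.4 ceiling
        (2.0, 1.41, [2.0] * 5, False),   # clone above the ceiling
        (1.9, 1.4, [2.0] * 5, True),     # difference exactly 0.5
        (1.88, 1.4, [2.0] * 5, False),   # difference below 0.5
        (2.0, 1.0, [1.6, 1.6, 1.6, 1.0, 1.0], True),   # 3/5 = 60% panel
        (2.0, 1.0, [1.6, 1.6, 1.0, 1.0, 1.0], False),  # 2/5 < 60%
    ])
    def test_deletion_clause_boundaries(self, tissue, clone, others, should_pass):
        ok, _ = self._run(tissue, clone, others)
        assert ok is should_pass

    @pytest.mark.parametrize("tissue,clone,others,should_pass", [
        (2.0, 2.61, [2.0] * 5, True),
        (2.0, 2.6, [2.0] * 5, False),    # clone must exceed 2.6 strictly
        (2.4, 2.91, [2.0] * 5, True),    # tissue exactly at 2.4 (mirror rule)
        (2.41, 3.0, [2.0] * 5, False),
        (2.0, 2.7, [2.4] * 5, False),    # others must be below 2.4 strictly
        (2.0, 2.7, [2.39] * 5, True),
    ])
    def test_duplication_clause_boundaries(self, tissue, clone, others, should_pass):
        ok, _ = self._run(tissue, clone, others, sv_type="DUP")
        assert ok is should_pass

    def test_duplication_as_printed_reading(self):
        cfg = PipelineConfig(dup_tissue_as_printed=True)
        ok, _ = self._run(2.5, 3.0, [2.0] * 5, sv_type="DUP", cfg=cfg)
        assert ok
        ok, _ = self._run(2.3, 3.0, [2.0] * 5, sv_type="DUP", cfg=cfg)
        assert not ok

    def test_gap_exclusion_within_one_megabase(self):
        ok, reasons = self._run(2.0, 1.0, [2.0] * 5,
                                gaps=[("chr1", 500_000, 501_000)])
        assert not ok and any("gap" in r for r in reasons)
        ok, _ = self._run(2.0, 1.0, [2.0] * 5,
                          gaps=[("chr1", 1_100_000, 1_101_000)])
        assert ok

    def test_missing_panel_profile_fails(self):
        cns = {"tissue": 2.0, "clone": 1.0, "o0": 2.0}
        ok, reasons = cnv_depth_filter(_profiles(cns), self.SPAN, "DEL",
                                       "tissue", "clone", self.OTHERS,
                                       config=CFG)
        assert not ok and "insufficient panel" in reasons[0]

    def test_every_failure_lists_the_violated_clause(self):
        ok, reasons = self._run(1.5, 1.5, [1.0] * 5)
        assert not ok and len(reasons) >= 3


class TestGenotypeAll:
    def test_absent_samples_get_upper_bound(self, small_ref):
        model = _model(small_ref)
        pseudo = build_pseudoreference(model.contig_sequence, small_ref, model)
        j = pseudo.alt_diagnostic[0]
        alt_reads = [AlignmentRecord("carrier", f"a{i}", "chr1", 14_000, "+",
                                     150, 0, 0, pseudo.sequence[j - 75:j + 75])
                     for i in range(10)]
        results = genotype_all({"carrier": alt_reads, "empty": []}, pseudo, CFG)
        by = {r.sample_id: r for r in results}
        assert by["carrier"].present
        assert not by["empty"].present
        assert by["empty"].af_upper_bound == pytest.approx(0.5 / 10)
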