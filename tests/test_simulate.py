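import numpy as np
import pytest
from scipy.stats import binomtest

from mosaicsv.alleles import AltAlleleSpec, implant_sv
from mosaicsv.genome import Segment, build_reference
from mosaicsv.simulate import (CloneSpec, build_haplotypes, project_read,
                               simulate_clone_reads, simulate_mda_chimeras,
                               simulate_read_depth)


def _deletion_scenario(seed, deleted=800, fraction=1.0, coverage=30.0):
    ref = build_reference(seed, 2, 30_000, snp_density=0.0005)
    spec = AltAlleleSpec(anchor=("chr1", 15_000), deleted_span=deleted,
                         chain=[], junction_mh=[2], label="d")
    _alt, truth = implant_sv(ref, spec)
    clone = CloneSpec(clone_id="c", harbored_svs=[("d", fraction)],
                      coverage=coverage)
    return ref, {"d": truth}, clone


def test_pair_count_matches_coverage_identity():
    ref = build_reference(2, 2, 50_000, snp_density=0)
    clone = CloneSpec(clone_id="c", coverage=30, read_length=150)
    reads = simulate_clone_reads(ref, [clone], {}, seed=4)["c"]
    expected_pairs = 30 * ref.total_length / (2 * 150)
    assert abs(len(reads) / 2 - expected_pairs) <= 0.05 * expected_pairs
    # coverage conservation: aligned+clipped bases over genome length
    total_bases = sum(len(r.sequence) for r in reads)
    assert abs(total_bases / ref.total_length - 30) <= 0.05 * 30


def test_identical_seeds_reproduce_identical_streams():
    ref1, truth1, clone = _deletion_scenario(21)
    ref2, truth2, _ = _deletion_scenario(21)
    r1 = simulate_clone_reads(ref1, [clone], truth1, seed=5)["c"]
    r2 = simulate_clone_reads(ref2, [clone], truth2, seed=5)["c"]
    assert len(r1) == len(r2)
    for a, b in zip(r1[:200], r2[:200]):
        assert (a.contig, a.pos, a.cigar, a.sequence) == \
            (b.contig, b.pos, b.cigar, b.sequence)


def test_junction_read_projection_geometry():
    """A read crossing a block junction is soft-clipped at the boundary and
    the larger side is kept as primary."""
    from mosaicsv.simulate import _Haplotype

    hap = _Haplotype()
    hap.contigs["c"] = "A" * 2000
    hap.blocks["c"] = [(0, 1000, Segment("x", 0, 1000)),
                       (1000, 2000, Segment("y", 5000, 6000))]
    hap.block_starts["c"] = [0, 1000]
    # read starts 40 bp before the junction: 40 bases on x, 110 on y
    contig, pos, strand, alen, cl, cr, _seq = project_read(hap, "c", 960, 1110,
                                                           "A" * 150)
    assert (contig, pos, strand) == ("y", 5000, "+")
    assert (cl, cr, alen) == (40, 0, 110)
    # mirror case: larger part before the junction
    contig, pos, strand, alen, cl, cr, _seq = project_read(hap, "c", 890, 1040,
                                                           "A" * 150)
    assert (contig, pos, alen, cl, cr) == ("x", 890, 110, 0, 40)


def test_reverse_block_projection_swaps_clips():
    from mosaicsv.genome import revcomp
    from mosaicsv.simulate import _Haplotype

    hap = _Haplotype()
    hap.contigs["c"] = "ACGT" * 500
    hap.blocks["c"] = [(0, 1000, Segment("x", 0, 1000)),
                       (1000, 2000, Segment("x", 3000, 4000, "reverse"))]
    hap.block_starts["c"] = [0, 1000]
    seq = hap.contigs["c"][980: 1130]
    contig, pos, strand, alen, cl, cr, out = project_read(hap, "c", 980, 1130, seq)
    assert strand == "-" and contig == "x"
    # 130 bases inside the reverse block map to its far end
    assert pos == 4000 - 130 and alen == 130
    assert (cl, cr) == (0, 20)       # alt-left clip becomes reference-right
    assert out == revcomp(seq)


@pytest.mark.parametrize("fraction", [1.0, 0.4, 0.1])
def test_junction_allele_fraction_tracks_cell_fraction(fraction):
    """ALT junction reads appear at ~cell_fraction/2 of junction-spanning
    reads (heterozygous SV), within a binomial 95% band."""
    ref, truth, clone = _deletion_scenario(33, fraction=fraction, coverage=60)
    reads = simulate_clone_reads(ref, [clone], truth, seed=8)["c"]
    j = 15_000
    alt = sum(1 for r in reads if r.clip_right > 5 and abs(r.end - j) <= 2)
    alt += sum(1 for r in reads if r.clip_left > 5 and abs(r.pos - j - 800) <= 2)
    ref_n = sum(1 for r in reads
                if r.max_clip == 0 and r.contig == "chr1"
                and r.pos + 5 <= j <= r.end - 5)
    assert alt + ref_n > 10
    p = binomtest(alt, alt + ref_n, fraction / 2).pvalue
    assert p > 0.01, (alt, ref_n, fraction)


def test_clone_private_snv_placement_avoids_sv_loci():
    from mosaicsv.simulate import _place_private_snvs

    ref, truth, clone = _deletion_scenario(44)
    clone.unique_snv_count = 40
    rng = np.random.default_rng(0)
    sites = _place_private_snvs(ref, truth, clone, rng)
    assert len(sites) == 40
    for c, p, *_ in sites:
        if c == "chr1":
            assert not (12_000 <= p <= 18_800)


def test_deletion_straddling_pairs_have_inflated_inserts():
    ref, truth, clone = _deletion_scenario(55, deleted=1000)
    reads = simulate_clone_reads(ref, [clone], truth, seed=9)["c"]
    straddle = [r.insert_size for r in reads
                if r.insert_size and r.insert_size > 900 and r.contig == "chr1"
                and r.pos < 15_000 < r.mate_pos + 150]
    assert straddle and np.mean(straddle) > 1000


def test_mda_rate_zero_yields_no_records():
    ref = build_reference(6, 2, 20_000, snp_density=0)
    assert simulate_mda_chimeras(ref, rate=0, seed=1) == []
    with pytest.raises(ValueError):
        simulate_mda_chimeras(ref, rate=-1, seed=1)


def test_mda_records_form_foldback_plus_duplication_pattern():
    ref = build_reference(6, 2, 50_000, snp_density=0)
    recs = simulate_mda_chimeras(ref, rate=4, seed=3, sample_id="s")
    assert recs
    assert all(r.max_clip >= 40 for r in recs)
    # artifact loci are never part of any truth set by construction
    assert all(":mda" in r.read_id for r in recs)


def test_read_depth_copy_number():
    ref, truth, clone = _deletion_scenario(66, deleted=10_000)
    # enlarge the deletion footprint by rebuilding explicitly
    ref = build_reference(66, 2, 40_000, snp_density=0.0005)
    spec = AltAlleleSpec(anchor=("chr1", 20_000), deleted_span=10_000,
                         chain=[], junction_mh=[0], label="d")
    _a, tr = implant_sv(ref, spec)
    clones = [CloneSpec(clone_id="carrier", harbored_svs=[("d", 1.0)], coverage=30),
              CloneSpec(clone_id="bulk", coverage=30)]
    depth = simulate_read_depth(ref, clones, {"d": tr}, bin_size=200, seed=2)
    inside = depth[(depth.contig == "chr1") & (depth.bin_start >= 20_000)
                   & (depth.bin_start < 30_000)]
    carrier_cn = inside[inside["sample"] == "carrier"].norm_cn.mean()
    bulk_cn = inside[inside["sample"] == "bulk"].norm_cn.mean()
    assert abs(carrier_cn - 1.0) < 0.15     # heterozygous clonal loss
    assert abs(bulk_cn - 2.0) < 0.15        # 0% carrier cells
    diploid = depth[(depth["sample"] == "bulk")]
    assert 1.95 <= diploid.norm_cn.mean() <= 2.05
    with pytest.raises(ValueError):
        simulate_read_depth(ref, clones, {"d": tr}, bin_size=20, seed=2)


def test_low_coverage_junction_warning():
    ref, truth, clone = _deletion_scenario(77)
    clone.coverage = 1.0
    with pytest.warns(UserWarning):
        simulate_clone_reads(ref, [clone], truth, seed=3)


def test_haplotype2_carries_het_snps():
    ref = build_reference(88, 1, 20_000, snp_density=0.002)
    clone = CloneSpec(clone_id="c", coverage=30)
    h1, h2 = build_haplotypes(ref, clone, {}, [])
    c, p, ref_base, alt = ref.het_snp_sites[0]
    assert h1.contigs[c][p] == ref_base
    assert h2.contigs[c][p] == alt
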