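"""Pseudoreference genotyping, clonality calls and the read-depth post-filter.

A pseudoreference is the resolved alternate allele flanked by reference
sequence; every sample is genotyped by counting reads that map uniquely to
the ALT or the REF version of the locus and cross a diagnostic position (a
junction).  Because the SV allele offers many diagnostic positions, this is
more sensitive than SNV genotyping at the same coverage, and the observed
carrier read capacity extrapolates to an allele-fraction upper bound for
samples with zero supporting reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import binomtest

from .config import DEFAULT_CONFIG, PipelineConfig
from .genome import ReferenceGenome, revcomp
from .rearrangement import RearrangementModel
from .simulate import AlignmentRecord

import edlib

log = logging.getLogger("mosaicsv.genotyping")


@dataclass
class PseudoReference:
    """ALT allele with reference flanks, plus its REF-allele counterpart."""

    sequence: str                # left flank + contig + right flank
    ref_sequence: str            # left flank + reference span + right flank
    contig: str                  # anchor contig
    flank: int
    left_flank_start: int        # reference coordinate of sequence[0]
    right_flank_end: int
    alt_diagnostic: list[int]    # junction positions in pseudo coordinates
    ref_diagnostic: list[int]    # anchor positions in ref-counterpart coordinates
    reverted_site_log: list[tuple[str, int]] = field(default_factory=list)
    source_call_id: str = ""


def build_pseudoreference(contig_seq: str, ref: ReferenceGenome,
                          model: RearrangementModel,
                          snp_panel: list[tuple[str, int, str, str]] | None = None,
                          config: PipelineConfig = DEFAULT_CONFIG,
                          source_call_id: str = "") -> PseudoReference:
    """Concatenate the assembled contig with reference flanks.

    Flanks are taken from the reference around the contig's outer anchor
    coordinates (truncated and logged near contig ends).  Homozygous SNPs
    from the panel falling in the flanks are reverted to the reference
    base, so a read cannot map to the ALT allele merely because of a
    homozygous difference from the reference; heterozygous sites are left
    untouched (the panel carries only homozygous sites).
    """
    if not contig_seq:
        raise ValueError("empty contig")
    if not model.chain and model.anchor_end == model.anchor_start:
        raise ValueError("model resolves to no allele")
    anchor_contig = model.anchor_region[0]
    a0, a1 = model.anchor_start, model.anchor_end
    ref_seq = ref.contigs[anchor_contig]
    f = config.flank
    left_start = max(0, a0 - f)
    right_end = min(len(ref_seq), a1 + f)
    if left_start == 0 or right_end == len(ref_seq):
        log.info("pseudoreference flank truncated at contig end")

    left = list(ref_seq[left_start:a0])
    right = list(ref_seq[a1:right_end])
    reverted: list[tuple[str, int]] = []
    for sc, pos, ref_base, _alt in (snp_panel or []):
        if sc != anchor_contig:
            continue
        if left_start <= pos < a0:
            if left[pos - left_start] != ref_base:
                reverted.append((sc, pos))
            left[pos - left_start] = ref_base
        elif a1 <= pos < right_end:
            if right[pos - a1] != ref_base:
                reverted.append((sc, pos))
            right[pos - a1] = ref_base

    # ALT pseudo: flanks + alternate span (the chain sequence)
    alt_interior = "".join(ref.fetch(seg) for seg in model.chain)
    pseudo = "".join(left) + alt_interior + "".join(right)
    ref_counterpart = "".join(left) + ref_seq[a0:a1] + "".join(right)

    # ALT-diagnostic positions: every junction of the chain in pseudo coords
    offs = [len(left)]
    for seg in model.chain:
        offs.append(offs[-1] + len(seg))
    alt_diag = sorted(set(offs))
    ref_diag = [len(left), len(left) + (a1 - a0)]
    return PseudoReference(
        sequence=pseudo, ref_sequence=ref_counterpart, contig=anchor_contig,
        flank=f, left_flank_start=left_start, right_flank_end=right_end,
        alt_diagnostic=alt_diag, ref_diagnostic=sorted(set(ref_diag)),
        reverted_site_log=reverted, source_call_id=source_call_id)


def call_homozygous_sites(site_alt_fractions: dict[tuple[str, int], list[float]],
                          site_bases: dict[tuple[str, int], tuple[str, str]],
                          config: PipelineConfig = DEFAULT_CONFIG,
                          ) -> list[tuple[str, int, str, str]]:
    """Panel of homozygous non-reference sites from per-clone ALT fractions.

    A site is homozygous when its ALT fraction is at least ``hom_fraction``
    in at least ``hom_sample_fraction`` of the same-brain clones.
    """
    panel = []
    for key, fracs in site_alt_fractions.items():
        if not fracs:
            continue
        n_hom = sum(1 for x in fracs if x >= config.hom_fraction)
        if n_hom >= config.hom_sample_fraction * len(fracs):
            ref_base, alt_base = site_bases[key]
            panel.append((key[0], key[1], ref_base, alt_base))
    return sorted(panel)


# ---------------------------------------------------------------------------
# unique mapping and genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeResult:
    sample_id: str
    unique_alt_reads: int
    unique_ref_reads: int
    allele_fraction: float
    af_upper_bound: float | None = None   # attached when unique_alt_reads == 0
    present: bool = False


def _best_hit(seq: str, target: str):
    """(edit distance, [start, end)) of the best infix alignment."""
    fwd = edlib.align(seq, target, mode="HW", task="locations")
    rev = edlib.align(revcomp(seq), target, mode="HW", task="locations")
    pick = fwd if (rev["editDistance"] < 0
                   or 0 <= fwd["editDistance"] <= rev["editDistance"]) else rev
    if pick["editDistance"] < 0 or not pick["locations"]:
        return None
    s, e = pick["locations"][0]
    return pick["editDistance"], (s, e + 1)


def map_reads_unique(reads: list[AlignmentRecord], pseudo: PseudoReference,
                     config: PipelineConfig = DEFAULT_CONFIG,
                     ) -> tuple[int, int]:
    """(unique ALT reads, unique REF reads) for one sample.

    A read counts for an allele iff its best alignment to that allele beats
    the other allele by at least ``unique_margin`` edits AND it crosses a
    diagnostic position (a junction).  Reads lying wholly in a flank exist
    in both alleles and count for neither.
    """
    margin = config.unique_margin
    n_alt = n_ref = 0
    for r in reads:
        alt_hit = _best_hit(r.sequence, pseudo.sequence)
        ref_hit = _best_hit(r.sequence, pseudo.ref_sequence)
        d_alt = alt_hit[0] if alt_hit else 10**9
        d_ref = ref_hit[0] if ref_hit else 10**9
        if alt_hit and d_ref - d_alt >= margin:
            s, e = alt_hit[1]
            if any(s < j < e for j in pseudo.alt_diagnostic):
                n_alt += 1
        elif ref_hit and d_alt - d_ref >= margin:
            s, e = ref_hit[1]
            if any(s < j < e for j in pseudo.ref_diagnostic):
                n_ref += 1
    return n_alt, n_ref


def _locus_reads(reads: list[AlignmentRecord], pseudo: PseudoReference,
                 config: PipelineConfig) -> list[AlignmentRecord]:
    """Reads whose reference projection overlaps the pseudo locus (speed cut)."""
    lo = pseudo.left_flank_start
    hi = pseudo.right_flank_end
    out = []
    for r in reads:
        if r.contig == pseudo.contig and r.end >= lo and r.pos <= hi:
            out.append(r)
        elif r.max_clip > 0 or (r.mate_contig and r.mate_contig != r.contig):
            # clipped / inter-contig reads may belong to distal chain segments
            out.append(r)
    return out


def genotype_all(samples: dict[str, list[AlignmentRecord]],
                 pseudo: PseudoReference,
                 config: PipelineConfig = DEFAULT_CONFIG) -> list[GenotypeResult]:
    """Genotype every sample against one pseudoreference.

    Samples with unique ALT reads are present; absent samples get an
    allele-fraction upper bound extrapolated from the carriers' read
    capacity (0.5 / N, see :func:`af_upper_bound`).
    """
    results = []
    for sample_id, reads in samples.items():
        n_alt, n_ref = map_reads_unique(_locus_reads(reads, pseudo, config),
                                        pseudo, config)
        total = n_alt + n_ref
        af = n_alt / total if total else 0.0
        results.append(GenotypeResult(sample_id, n_alt, n_ref, af,
                                      present=n_alt > 0))
    capacity = max((r.unique_alt_reads + r.unique_ref_reads
                    for r in results if r.present), default=0)
    for r in results:
        if not r.present:
            r.af_upper_bound = af_upper_bound(capacity) if capacity else None
    return results


def af_upper_bound(unique_read_capacity_n: int) -> float:
    """Largest allele fraction consistent with zero supporting reads.

    The carrier's N diagnostic reads correspond to ~50% allele fraction, so
    one read corresponds to 0.5/N; observing zero reads bounds the fraction
    below that.  N = 167 gives 0.30%.
    """
    if unique_read_capacity_n < 1:
        raise ValueError("no assay capacity (N must be >= 1)")
    return 0.5 / unique_read_capacity_n


def classify_clonality(genotype: GenotypeResult,
                       het_sites_deleted_region: list[tuple[int, int]] | None = None,
                       config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """'clonal' or 'subclonal' for a carrier genotype.

    Subclonal iff the allele fraction is significantly below 0.5 (binomial
    test at ``clonality_alpha``) OR any heterozygous SNP inside the deleted
    region still shows both alleles in the clone's reads (two haplotypes
    persist, whereas a clonal deletion leaves only one).
    ``het_sites_deleted_region`` holds (ref_reads, alt_reads) observed at
    each such site.
    """
    for ref_n, alt_n in het_sites_deleted_region or []:
        if ref_n > 0 and alt_n > 0:
            return "subclonal"
    n = genotype.unique_alt_reads + genotype.unique_ref_reads
    if n == 0:
        return "subclonal"
    test = binomtest(genotype.unique_alt_reads, n, 0.5, alternative="less")
    if test.pvalue < config.clonality_alpha:
        return "subclonal"
    return "clonal"


# ---------------------------------------------------------------------------
# read-depth CNV post-filter
# ---------------------------------------------------------------------------

def _region_cn(profiles, sample: str, contig: str, start: int, end: int) -> float | None:
    df = profiles
    sel = df[(df["sample"] == sample) & (df["contig"] == contig)]
    if sel.empty:
        return None
    bin_size = int(sel["bin_start"].iloc[1] - sel["bin_start"].iloc[0]) \
        if len(sel) > 1 else 200
    sel = sel[(sel["bin_start"] + bin_size > start) & (sel["bin_start"] < end)]
    if sel.empty:
        return None
    # decisions flip exactly at the printed thresholds: shield the boundary
    # comparisons from float averaging noise
    return round(float(sel["norm_cn"].mean()), 9)


def cnv_depth_filter(profiles, call_span: tuple[str, int, int], sv_type: str,
                     tissue_id: str, clone_id: str, other_clone_ids: list[str],
                     gaps: list[tuple[str, int, int]] | None = None,
                     config: PipelineConfig = DEFAULT_CONFIG,
                     ) -> tuple[bool, list[str]]:
    """Read-depth copy-number post-filter for a DEL or DUP call.

    Deletion passes iff tissue CN >= 1.6, clone CN <= 1.4, (tissue - clone)
    >= 0.5, at least 60% of the other clones have CN >= 1.6, and the call
    is more than 1 Mb from any reference gap.  The duplication clauses are
    the mirror image (clone > 2.6, tissue <= 2.4, others < 2.4); setting
    ``dup_tissue_as_printed`` instead requires tissue >= 2.4.  Returns
    (passed, list of violated clauses).
    """
    contig, start, end = call_span
    reasons: list[str] = []

    for gc, gs, ge in gaps or []:
        if gc == contig and start < ge + config.gap_exclusion \
                and end > gs - config.gap_exclusion:
            reasons.append(f"within {config.gap_exclusion} bp of reference gap")
            break

    tissue_cn = _region_cn(profiles, tissue_id, contig, start, end)
    clone_cn = _region_cn(profiles, clone_id, contig, start, end)
    if tissue_cn is None or clone_cn is None:
        return False, ["insufficient panel: missing tissue or clone profile"]
    others = []
    for oc in other_clone_ids:
        cn = _region_cn(profiles, oc, contig, start, end)
        if cn is None:
            return False, [f"insufficient panel: missing profile for {oc}"]
        others.append(cn)

    if sv_type == "DEL":
        if tissue_cn < config.del_tissue_min:
            reasons.append(f"tissue CN {tissue_cn:.2f} < {config.del_tissue_min}")
        if clone_cn > config.del_clone_max:
            reasons.append(f"clone CN {clone_cn:.2f} > {config.del_clone_max}")
        if tissue_cn - clone_cn < config.cn_difference:
            reasons.append("tissue - clone CN difference < "
                           f"{config.cn_difference}")
        if others:
            frac = sum(1 for cn in others if cn >= config.del_tissue_min) / len(others)
            if frac < config.clone_majority:
                reasons.append(f"only {frac:.0%} of other clones have CN >= "
                               f"{config.del_tissue_min}")
    elif sv_type == "DUP":
        if clone_cn <= config.dup_clone_min:
            reasons.append(f"clone CN {clone_cn:.2f} <= {config.dup_clone_min}")
        if config.dup_tissue_as_printed:
            if tissue_cn < config.dup_other_max:
                reasons.append(f"tissue CN {tissue_cn:.2f} < {config.dup_other_max}")
        else:
            if tissue_cn > config.dup_other_max:
                reasons.append(f"tissue CN {tissue_cn:.2f} > {config.dup_other_max}")
        if clone_cn - tissue_cn < config.cn_difference:
            reasons.append("clone - tissue CN difference < "
                           f"{config.cn_difference}")
        if others:
            frac = sum(1 for cn in others if cn < config.dup_other_max) / len(others)
            if frac < config.clone_majority:
                reasons.append(f"only {frac:.0%} of other clones have CN < "
                               f"{config.dup_other_max}")
    else:
        raise ValueError(f"depth filter applies to DEL/DUP, not {sv_type}")
    return (not reasons), reasons
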