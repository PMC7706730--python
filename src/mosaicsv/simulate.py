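"""Haplotype-aware paired-end read simulation for clone sequencing.

Each clone is modeled as a diploid population: haplotype 1 is the reference
(plus homozygous SNPs), haplotype 2 additionally carries the heterozygous
germline SNPs, the clone-private somatic SNVs and the clone's SV alleles.
Fragments are drawn from the two haplotypes in equal proportion, so a
heterozygous SV carried by a fraction ``f`` of the cells yields junction
reads at allele fraction ``f/2`` (0.5 for clonal events).  Reads are then
projected onto the reference the way an aligner would report them: reads
wholly inside one collinear block map contiguously, reads crossing an
alternate junction carry soft clips, mates falling in segments from other
chromosomes get inter-contig mate fields, and pairs straddling a deletion
show inflated insert sizes.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alleles import TruthRecord
from .genome import ReferenceGenome, Segment, revcomp

_BASES = "ACGT"


@dataclass
class AlignmentRecord:
    """One read of a pair projected onto the reference."""

    sample_id: str
    read_id: str
    contig: str
    pos: int                 # 0-based reference start of the aligned portion
    strand: str              # reference strand of the aligned portion
    aligned_len: int
    clip_left: int           # soft-clip lengths in reference orientation
    clip_right: int
    sequence: str            # full read in reference-forward orientation
    mapq: int = 60
    mate_contig: str | None = None
    mate_pos: int | None = None
    insert_size: int | None = None   # outer distance; None for inter-contig pairs
    is_proper_pair: bool = False

    @property
    def end(self) -> int:
        return self.pos + self.aligned_len

    @property
    def max_clip(self) -> int:
        return max(self.clip_left, self.clip_right)

    @property
    def clipped_left_seq(self) -> str:
        return self.sequence[:self.clip_left]

    @property
    def clipped_right_seq(self) -> str:
        return self.sequence[len(self.sequence) - self.clip_right:]

    @property
    def cigar(self) -> str:
        parts = []
        if self.clip_left:
            parts.append(f"{self.clip_left}S")
        parts.append(f"{self.aligned_len}M")
        if self.clip_right:
            parts.append(f"{self.clip_right}S")
        return "".join(parts)


@dataclass
class CloneSpec:
    """Sequencing sample: a clone, tissue bulk, or unrelated control.

    ``harbored_svs`` lists (allele label, cell fraction); clonal events have
    cell fraction 1.0 (allele fraction 0.5 for a heterozygous SV).
    ``unique_snv_count`` clone-private somatic SNVs are embedded at allele
    fraction 0.5, outside SV spans.  ``mda`` marks samples amplified by
    multiple displacement amplification, for which inverted-chimera
    artifacts are injected.
    """

    clone_id: str
    brain_id: str = "brain1"
    harbored_svs: list[tuple[str, float]] = field(default_factory=list)
    unique_snv_count: int = 0
    mda: bool = False
    coverage: float = 30.0
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    read_length: int = 150
    base_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for label, f in self.harbored_svs:
            if not 0 <= f <= 1:
                raise ValueError(f"cell fraction for {label} must be in [0, 1]")


# ---------------------------------------------------------------------------
# haplotype construction
# ---------------------------------------------------------------------------

class _Haplotype:
    """A genome as collinear blocks over (possibly edited) base sequences."""

    def __init__(self) -> None:
        self.contigs: dict[str, str] = {}
        # per alt contig: sorted block starts and (alt_start, alt_end, Segment)
        self.blocks: dict[str, list[tuple[int, int, Segment]]] = {}
        self.block_starts: dict[str, list[int]] = {}
        # alt-coordinate regions occupied by each allele: label -> (contig, a0, a1, fraction)
        self.allele_regions: list[tuple[str, str, int, int, float]] = []

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def _apply_snvs(seq: dict[str, list[str]], sites) -> None:
    for contig, pos, _ref, alt in sites:
        seq[contig][pos] = alt


def build_haplotypes(ref: ReferenceGenome, clone: CloneSpec,
                     truth: dict[str, TruthRecord],
                     private_snvs: list[tuple[str, int, str, str]],
                     ) -> tuple[_Haplotype, _Haplotype]:
    """(haplotype1, haplotype2) genomes for a clone."""
    base1 = {c: list(s) for c, s in ref.contigs.items()}
    _apply_snvs(base1, ref.hom_snp_sites)
    base2 = {c: list(s) for c, s in base1.items()}
    _apply_snvs(base2, ref.het_snp_sites)
    _apply_snvs(base2, private_snvs)
    base1 = {c: "".join(s) for c, s in base1.items()}
    base2 = {c: "".join(s) for c, s in base2.items()}

    h1 = _Haplotype()
    h1.contigs = base1
    for c, s in base1.items():
        h1.blocks[c] = [(0, len(s), Segment(c, 0, len(s), "forward"))]
        h1.block_starts[c] = [0]

    h2 = _Haplotype()
    per_contig: dict[str, list[tuple[TruthRecord, float]]] = {}
    for label, frac in clone.harbored_svs:
        tr = truth[label]
        per_contig.setdefault(tr.anchor_contig, []).append((tr, frac))

    for contig, base_seq in base2.items():
        alleles = sorted(per_contig.get(contig, []), key=lambda t: t[0].anchor_start)
        for i in range(1, len(alleles)):
            if alleles[i][0].anchor_start < alleles[i - 1][0].anchor_end:
                raise ValueError("overlapping alleles on one contig are unsupported")
        blocks: list[tuple[int, int, Segment]] = []
        pieces: list[str] = []
        cursor_ref = 0
        cursor_alt = 0

        def emit(seg: Segment, fetch_from: dict[str, str]) -> None:
            nonlocal cursor_alt
            s = fetch_from[seg.contig][seg.start:seg.end]
            if seg.is_reverse:
                s = revcomp(s)
            blocks.append((cursor_alt, cursor_alt + len(s), seg))
            pieces.append(s)
            cursor_alt += len(s)

        for tr, frac in alleles:
            if tr.anchor_start > cursor_ref:
                emit(Segment(contig, cursor_ref, tr.anchor_start, "forward"),
                     {contig: base_seq})
            locus_start = cursor_alt
            for seg in tr.chain:
                emit(seg, base2)
            locus_end = cursor_alt
            # include a junction pad so fraction-resampling also covers pure
            # deletions (whose alt locus is a single point)
            h2.allele_regions.append((tr.label, contig,
                                      max(0, locus_start - 1), locus_end + 1, frac))
            cursor_ref = tr.anchor_end
        if cursor_ref < len(base_seq):
            emit(Segment(contig, cursor_ref, len(base_seq), "forward"),
                 {contig: base_seq})
        h2.contigs[contig] = "".join(pieces)
        h2.blocks[contig] = blocks
        h2.block_starts[contig] = [b[0] for b in blocks]
    return h1, h2


# ---------------------------------------------------------------------------
# projection (aligner emulation)
# ---------------------------------------------------------------------------

def project_read(hap: _Haplotype, contig: str, r0: int, r1: int,
                 read_seq: str) -> tuple[str, int, str, int, int, int, str]:
    """Project alt-genome read interval [r0, r1) onto the reference.

    Returns (ref_contig, ref_pos, strand, aligned_len, clip_left,
    clip_right, sequence_in_ref_forward_orientation).  The primary block is
    the one with the largest overlap (left-most on ties), emulating an
    aligner that soft-clips the bases extending past the junction.
    """
    blocks = hap.blocks[contig]
    starts = hap.block_starts[contig]
    i = bisect.bisect_right(starts, r0) - 1
    best = None
    j = max(i, 0)
    while j < len(blocks) and blocks[j][0] < r1:
        b0, b1, seg = blocks[j]
        ov = min(r1, b1) - max(r0, b0)
        if ov > 0 and (best is None or ov > best[0]):
            best = (ov, b0, b1, seg)
        j += 1
    if best is None:
        raise ValueError("read interval outside genome")
    _ov, b0, b1, seg = best
    ov0, ov1 = max(r0, b0), min(r1, b1)
    if seg.orientation == "forward":
        pos = seg.start + (ov0 - b0)
        return (seg.contig, pos, "+", ov1 - ov0, ov0 - r0, r1 - ov1, read_seq)
    pos = seg.end - (ov1 - b0)
    return (seg.contig, pos, "-", ov1 - ov0, r1 - ov1, ov0 - r0, revcomp(read_seq))


def _add_errors(seq: str, rng: np.random.Generator, k: int) -> str:
    if k <= 0:
        return seq
    s = list(seq)
    for pos in rng.choice(len(seq), size=min(k, len(seq)), replace=False):
        cur = s[pos]
        s[pos] = _BASES[(_BASES.index(cur) + int(rng.integers(1, 4))) % 4] \
            if cur in _BASES else "A"
    return "".join(s)


def _pair_records(sample_id: str, read_id: str, hap: _Haplotype, contig: str,
                  f0: int, f1: int, rl: int, rng: np.random.Generator,
                  err: float, err_k: tuple[int, int] = (-1, -1)) -> list[AlignmentRecord]:
    g = hap.contigs[contig]
    k1, k2 = err_k
    if k1 < 0:
        k1 = rng.binomial(rl, err) if err > 0 else 0
        k2 = rng.binomial(rl, err) if err > 0 else 0
    seq1 = _add_errors(g[f0:f0 + rl], rng, k1)
    seq2 = _add_errors(g[f1 - rl:f1], rng, k2)
    p1 = project_read(hap, contig, f0, f0 + rl, seq1)
    p2 = project_read(hap, contig, f1 - rl, f1, seq2)
    recs = []
    for me, mate, tag in ((p1, p2, "/1"), (p2, p1, "/2")):
        c, pos, strand, alen, cl, cr, s = me
        mc, mpos = mate[0], mate[1]
        same = c == mc
        insert = None
        if same:
            lo = min(pos, mpos)
            hi = max(pos + alen, mpos + mate[3])
            insert = hi - lo
        proper = (same and cl == 0 and cr == 0 and mate[4] == 0 and mate[5] == 0
                  and strand == "+" and mate[2] == "+" and insert == f1 - f0)
        recs.append(AlignmentRecord(
            sample_id=sample_id, read_id=read_id + tag, contig=c, pos=pos,
            strand=strand, aligned_len=alen, clip_left=cl, clip_right=cr,
            sequence=s, mate_contig=mc, mate_pos=mpos,
            insert_size=insert if same else None, is_proper_pair=proper))
    return recs


# ---------------------------------------------------------------------------
# clone read simulation
# ---------------------------------------------------------------------------

def _place_private_snvs(ref: ReferenceGenome, truth: dict[str, TruthRecord],
                        clone: CloneSpec, rng: np.random.Generator,
                        pad: int = 3000) -> list[tuple[str, int, str, str]]:
    """Clone-private SNV sites, kept away from every SV locus."""
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for tr in truth.values():
        _c, rs, re_ = tr.region
        forbidden.setdefault(tr.anchor_contig, []).append((rs - pad, re_ + pad))
        for seg in tr.chain:
            forbidden.setdefault(seg.contig, []).append((seg.start - pad, seg.end + pad))
    names = list(ref.contigs)
    lengths = np.array([ref.length(c) for c in names], dtype=float)
    sites: list[tuple[str, int, str, str]] = []
    attempts = 0
    while len(sites) < clone.unique_snv_count and attempts < 100 * (clone.unique_snv_count + 1):
        attempts += 1
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        contig = names[ci]
        pos = int(rng.integers(0, ref.length(contig)))
        if any(a <= pos < b for a, b in forbidden.get(contig, [])):
            continue
        ref_base = ref.contigs[contig][pos]
        alt = _BASES[(_BASES.index(ref_base) + 1) % 4] if ref_base in _BASES else "A"
        sites.append((contig, pos, ref_base, alt))
    return sites


def simulate_clone_reads(ref: ReferenceGenome, clones: list[CloneSpec],
                         truth: dict[str, TruthRecord] | list[TruthRecord],
                         seed: int) -> dict[str, list[AlignmentRecord]]:
    """Simulate reference-projected paired-end alignments for each sample.

    Expected pair count per sample is ``coverage * genome_length /
    (2 * read_length)``; identical seeds and specs give identical output.
    eccDNA alleles additionally contribute circle-junction fragments in
    carrier samples.  MDA chimera artifacts are injected for samples with
    ``mda=True`` (see :func:`simulate_mda_chimeras`).
    """
    if isinstance(truth, list):
        truth = {t.label: t for t in truth}
    master = np.random.default_rng(seed)
    out: dict[str, list[AlignmentRecord]] = {}
    for clone in clones:
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        snvs = _place_private_snvs(ref, truth, clone, rng)
        h1, h2 = build_haplotypes(ref, clone, truth, snvs)

        rl = clone.read_length
        n_pairs = int(round(clone.coverage * ref.total_length / (2 * rl)))
        for lab, f in clone.harbored_svs:
            junction_rate = clone.coverage * f / 2 * (rl - 1) / rl
            if junction_rate < 1:
                warnings.warn(
                    f"{clone.clone_id}/{lab}: expected junction-spanning reads "
                    f"< 1 at this coverage", stacklevel=2)

        recs: list[AlignmentRecord] = []
        haps = (h1, h2)
        geom = []
        for h in haps:
            cnames = list(h.contigs)
            lens = [h.length(c) for c in cnames]
            geom.append((cnames, lens, sum(lens)))
        # batched randomness: haplotype choice, genome offset, fragment
        # length and per-read error counts for every pair up front
        hap_idx = rng.integers(0, 2, size=n_pairs)
        offsets = rng.random(n_pairs)
        frags = np.rint(rng.normal(clone.insert_mean, clone.insert_sd,
                                   size=n_pairs)).astype(int)
        if clone.base_error_rate > 0:
            err_ks = rng.binomial(rl, clone.base_error_rate, size=2 * n_pairs)
        else:
            err_ks = np.zeros(2 * n_pairs, dtype=int)
        for i in range(n_pairs):
            hap = haps[hap_idx[i]]
            cnames, lens, total = geom[hap_idx[i]]
            x = int(offsets[i] * total)
            for contig, L in zip(cnames, lens):
                if x < L:
                    break
                x -= L
            frag = max(rl, min(int(frags[i]), L))
            f0 = min(x, L - frag)
            f1 = f0 + frag
            if hap is h2:
                # subclonal alleles: a fragment overlapping the allele locus
                # is re-sourced from haplotype 1 with probability 1 - f
                for lab, acontig, a0, a1, f in h2.allele_regions:
                    if contig == acontig and f0 < a1 and f1 > a0 and f < 1.0:
                        if rng.random() > f:
                            hap = h1
                            tr = truth[lab]
                            shift = f0 - a0
                            f0 = min(max(0, tr.anchor_start + shift),
                                     h1.length(contig) - frag)
                            f1 = f0 + frag
                        break
            recs.extend(_pair_records(clone.clone_id, f"{clone.clone_id}:{i}",
                                      hap, contig, f0, f1, rl, rng,
                                      clone.base_error_rate,
                                      (int(err_ks[2 * i]), int(err_ks[2 * i + 1]))))

        # circle-junction fragments for eccDNA alleles
        for lab, f in clone.harbored_svs:
            tr = truth[lab]
            if not tr.eccdna:
                continue
            recs.extend(_eccdna_reads(h1, tr, clone, f, rng))

        if clone.mda:
            recs.extend(simulate_mda_chimeras(
                ref, rate=3.0, seed=int(rng.integers(0, 2**31 - 1)),
                sample_id=clone.clone_id, read_length=rl))
        out[clone.clone_id] = recs
    return out


def _eccdna_reads(h1: _Haplotype, tr: TruthRecord, clone: CloneSpec, f: float,
                  rng: np.random.Generator) -> list[AlignmentRecord]:
    """Fragments from the excised circle; the b→a junction projects as
    reciprocal clipped reads at both deletion breakpoints."""
    contig = tr.anchor_contig
    a, b = tr.anchor_start, tr.anchor_end
    circ_len = b - a
    rl = clone.read_length
    if circ_len < rl + 10:
        return []
    circle = _Haplotype()
    # doubled circle so wrap-around fragments stay contiguous strings
    circ_seq = h1.contigs[contig][a:b]
    circle.contigs["circ"] = circ_seq + circ_seq
    circle.blocks["circ"] = [
        (0, circ_len, Segment(contig, a, b, "forward")),
        (circ_len, 2 * circ_len, Segment(contig, a, b, "forward")),
    ]
    circle.block_starts["circ"] = [0, circ_len]
    n_pairs = int(round(clone.coverage * f / 2 * circ_len / (2 * rl)))
    recs: list[AlignmentRecord] = []
    frag_cap = min(circ_len, int(clone.insert_mean))
    for i in range(n_pairs):
        frag = int(round(rng.normal(min(clone.insert_mean, frag_cap), clone.insert_sd)))
        frag = max(rl, min(frag, circ_len))
        f0 = int(rng.integers(0, circ_len))
        recs.extend(_pair_records(clone.clone_id, f"{clone.clone_id}:ecc{i}",
                                  circle, "circ", f0, f0 + frag, rl, rng,
                                  clone.base_error_rate))
    return recs


# ---------------------------------------------------------------------------
# MDA chimera artifacts
# ---------------------------------------------------------------------------

def simulate_mda_chimeras(ref: ReferenceGenome, rate: float, seed: int,
                          sample_id: str = "mda_sample", read_length: int = 150,
                          reads_per_locus: int = 5) -> list[AlignmentRecord]:
    """Inject MDA-style chimera artifact reads.

    Each artifact locus combines a one-sided fold-back (inverted) junction
    with a short duplicated span starting within 1000 bp — the classic
    displaced-strand re-priming signature — with no consistent reciprocal
    breakend partner.  ``rate`` is the expected number of artifact loci per
    genome; rate 0 yields no records.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    n_loci = int(rng.poisson(rate))
    recs: list[AlignmentRecord] = []
    names = list(ref.contigs)
    rl = read_length
    for li in range(n_loci):
        contig = names[int(rng.integers(0, len(names)))]
        L = ref.length(contig)
        p = int(rng.integers(2 * rl + 600, L - 2 * rl - 600))
        seq = ref.contigs[contig]

        # (a) fold-back: reads aligned up to p whose clipped tail is the
        # reverse complement of the sequence just before p
        for k in range(reads_per_locus):
            clip = 40 + int(rng.integers(0, 30))
            alen = rl - clip
            read = seq[p - alen:p] + revcomp(seq[p - clip:p])
            recs.append(AlignmentRecord(
                sample_id=sample_id, read_id=f"{sample_id}:mda{li}a{k}",
                contig=contig, pos=p - alen, strand="+", aligned_len=alen,
                clip_left=0, clip_right=clip, sequence=read,
                mate_contig=contig, mate_pos=max(0, p - 400), insert_size=400,
                is_proper_pair=False))

        # (b) short duplicated span within 1000 bp of the fold-back
        q = p + int(rng.integers(150, 900))
        s = 120 + int(rng.integers(0, 180))
        for k in range(reads_per_locus):
            clip = 40 + int(rng.integers(0, 30))
            alen = rl - clip
            # right-clip at q+s continuing at q (tandem-duplication junction)
            read = seq[q + s - alen:q + s] + seq[q:q + clip]
            recs.append(AlignmentRecord(
                sample_id=sample_id, read_id=f"{sample_id}:mda{li}b{k}",
                contig=contig, pos=q + s - alen, strand="+", aligned_len=alen,
                clip_left=0, clip_right=clip, sequence=read,
                mate_contig=contig, mate_pos=max(0, q - 400), insert_size=400,
                is_proper_pair=False))
            # matching left-clip at q continuing from q+s
            read2 = seq[q + s - clip:q + s] + seq[q:q + alen]
            recs.append(AlignmentRecord(
                sample_id=sample_id, read_id=f"{sample_id}:mda{li}c{k}",
                contig=contig, pos=q, strand="+", aligned_len=alen,
                clip_left=clip, clip_right=0, sequence=read2,
                mate_contig=contig, mate_pos=min(L - rl, q + 400), insert_size=400,
                is_proper_pair=False))
    return recs


# ---------------------------------------------------------------------------
# read depth
# ---------------------------------------------------------------------------

def simulate_read_depth(ref: ReferenceGenome, clones: list[CloneSpec],
                        truth: dict[str, TruthRecord] | list[TruthRecord],
                        bin_size: int = 200, seed: int = 0):
    """Per-sample, per-bin read counts and normalized copy number.

    Counts are Poisson around the sample's coverage, scaled by the local
    copy number implied by the truth: a heterozygous clonal deletion halves
    the affected bins (CN 1.0), a duplication adds half a copy (CN 3.0),
    scaled by cell fraction for subclonal events.  Normalized CN is the
    count divided by the sample's genome-wide mean, times 2.
    """
    import pandas as pd

    if bin_size < 50:
        raise ValueError("bin_size must be >= 50")
    if isinstance(truth, list):
        truth = {t.label: t for t in truth}
    master = np.random.default_rng(seed)
    frames = []
    for clone in clones:
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        rows = []
        for contig, seq in ref.contigs.items():
            n_bins = len(seq) // bin_size
            factor = np.ones(n_bins)
            for lab, f in clone.harbored_svs:
                tr = truth[lab]
                for ev in tr.event_classes:
                    if ev.contig != contig:
                        continue
                    b0, b1 = ev.start // bin_size, -(-ev.end // bin_size)
                    if ev.kind == "DEL":
                        factor[b0:b1] *= 1 - f / 2
                    elif ev.kind == "DUP":
                        factor[b0:b1] *= 1 + f / 2
            lam = clone.coverage * bin_size / clone.read_length * factor
            counts = rng.poisson(lam)
            gap_mask = np.zeros(n_bins, dtype=bool)
            for gc, gs, ge in ref.gap_intervals:
                if gc == contig:
                    gap_mask[gs // bin_size:-(-ge // bin_size)] = True
            for b in range(n_bins):
                rows.append((clone.clone_id, contig, b * bin_size,
                             int(counts[b]), bool(gap_mask[b])))
        df = pd.DataFrame(rows, columns=["sample", "contig", "bin_start",
                                         "count", "in_gap"])
        mean = df["count"].mean()
        df["norm_cn"] = df["count"] / mean * 2.0
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
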