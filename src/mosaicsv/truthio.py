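"""Truth files: VCF 4.2 with breakend notation, plus a BED of spans.

Pure deletions are written as symbolic ``<DEL>`` records together with
their two-line breakend equivalent; complex alleles are written as one
breakend line per junction.  Enough structure (anchor, chain, requested
microhomologies, carriers) is carried in INFO to make write→read lossless.
"""

from __future__ import annotations

import os

import pysam

from .alleles import AltAlleleSpec, TruthRecord, make_truth_record
from .genome import ReferenceGenome, Segment

_HEADER_LINES = [
    '##fileformat=VCFv4.2',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=LABEL,Number=1,Type=String,Description="Allele label">',
    '##INFO=<ID=ANCHOR,Number=1,Type=String,Description="Anchor contig:start:deleted_span (0-based)">',
    '##INFO=<ID=CHAIN,Number=1,Type=String,Description="Alt segment chain contig:start-end:strand joined by |">',
    '##INFO=<ID=MH,Number=1,Type=String,Description="Requested junction microhomology lengths joined by |">',
    '##INFO=<ID=CARRIERS,Number=1,Type=String,Description="Carrier clone ids joined by |">',
    '##INFO=<ID=ECC,Number=0,Type=Flag,Description="Deleted span persists as an extrachromosomal circle">',
    '##ALT=<ID=DEL,Description="Deletion">',
]


def _bnd_alt(ref_base: str, donor_strand: str, mate_contig: str, mate_pos_1: int,
             acceptor_strand: str) -> str:
    mate = f"{mate_contig}:{mate_pos_1}"
    if donor_strand == "+" and acceptor_strand == "+":
        return f"{ref_base}[{mate}["
    if donor_strand == "+" and acceptor_strand == "-":
        return f"{ref_base}]{mate}]"
    if donor_strand == "-" and acceptor_strand == "+":
        return f"[{mate}[{ref_base}"
    return f"]{mate}]{ref_base}"


def _chain_str(chain: list[Segment]) -> str:
    return "|".join(f"{s.contig}:{s.start}-{s.end}:"
                    f"{'+' if s.orientation == 'forward' else '-'}"
                    for s in chain) or "."


def _parse_chain(text: str) -> list[Segment]:
    if text in (".", ""):
        return []
    out = []
    for part in text.split("|"):
        loc, strand = part.rsplit(":", 1)
        contig, span = loc.rsplit(":", 1)
        start, end = span.split("-")
        out.append(Segment(contig, int(start), int(end),
                           "forward" if strand == "+" else "reverse"))
    return out


def write_truth(truth: list[TruthRecord], ref: ReferenceGenome, vcf_path,
                bed_path=None) -> None:
    """Write truth records as a breakend VCF and a BED of reference spans."""
    lines = list(_HEADER_LINES)
    for name, seq in ref.contigs.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    for tr in truth:
        common = (f"LABEL={tr.label};ANCHOR={tr.anchor_contig}:{tr.anchor_start}:"
                  f"{tr.anchor_end - tr.anchor_start};CHAIN={_chain_str(tr.chain)};"
                  f"MH={'|'.join(map(str, tr.junction_mh))};"
                  f"CARRIERS={'|'.join(tr.carrier_clones) or '.'}"
                  + (";ECC" if tr.eccdna else ""))
        if not tr.chain and tr.anchor_end > tr.anchor_start:
            # symbolic deletion record: POS is the base before the deleted span
            pos1 = tr.anchor_start  # 1-based position of preceding base
            ref_base = ref.contigs[tr.anchor_contig][tr.anchor_start - 1] \
                if tr.anchor_start > 0 else "N"
            lines.append(
                f"{tr.anchor_contig}\t{pos1}\t{tr.label}\t{ref_base}\t<DEL>\t.\t"
                f"PASS\tSVTYPE=DEL;END={tr.anchor_end};{common}")
        for j, (cd, pd, sd, ca, pa, sa) in enumerate(tr.breakpoints):
            # donor-side breakend: REF base is the last donor base
            ref_idx = pd - 1 if sd == "+" else pd
            ref_idx = min(max(ref_idx, 0), ref.length(cd) - 1)
            ref_base = ref.contigs[cd][ref_idx]
            mate_pos1 = pa + 1 if sa == "+" else pa
            mate_pos1 = max(1, mate_pos1)
            alt = _bnd_alt(ref_base, sd, ca, mate_pos1, sa)
            bnd_id = f"{tr.label}_bnd{j}"
            info = f"SVTYPE=BND;MATEID={bnd_id}m;{common}" if j == 0 else \
                f"SVTYPE=BND;MATEID={bnd_id}m"
            lines.append(f"{cd}\t{max(1, ref_idx + 1)}\t{bnd_id}\t{ref_base}\t"
                         f"{alt}\t.\tPASS\t{info}")
            # mate record: the acceptor side of the same novel adjacency
            mate_idx = min(max(pa if sa == "+" else pa - 1, 0),
                           ref.length(ca) - 1)
            mate_base = ref.contigs[ca][mate_idx]
            back = _bnd_alt(mate_base, "-" if sa == "+" else "+",
                            cd, max(1, ref_idx + 1), "-" if sd == "+" else "+")
            lines.append(f"{ca}\t{mate_idx + 1}\t{bnd_id}m\t{mate_base}\t"
                         f"{back}\t.\tPASS\tSVTYPE=BND;MATEID={bnd_id}")

    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for tr in truth:
                c, s, e = tr.region
                fh.write(f"{c}\t{s}\t{max(e, s + 1)}\t{tr.label}\n")


def read_truth(vcf_path) -> list[TruthRecord]:
    """Read a truth VCF back into TruthRecords (lossless round-trip)."""
    out: list[TruthRecord] = []
    seen: set[str] = set()
    with pysam.VariantFile(os.fspath(vcf_path)) as vf:
        for rec in vf:
            info = dict(rec.info)
            label = info.get("LABEL")
            if label is None or label in seen:
                continue
            seen.add(label)
            anchor_contig, astart, dspan = str(info["ANCHOR"]).split(":")
            chain = _parse_chain(str(info["CHAIN"]))
            mh = [int(x) for x in str(info["MH"]).split("|")]
            spec = AltAlleleSpec(
                anchor=(anchor_contig, int(astart)),
                deleted_span=int(dspan), chain=chain, junction_mh=mh,
                label=str(label), eccdna=bool(info.get("ECC", False)))
            tr = make_truth_record(spec)
            carriers = str(info.get("CARRIERS", "."))
            if carriers not in (".", ""):
                tr.carrier_clones = carriers.split("|")
            out.append(tr)
    return out
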