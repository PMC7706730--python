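"""SAM import/export for projected alignment records (via pysam)."""

from __future__ import annotations

import os

import pysam

from .genome import ReferenceGenome
from .simulate import AlignmentRecord


def write_sam(records: list[AlignmentRecord], ref: ReferenceGenome, path) -> None:
    """Write alignment records as plain-text SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in ref.contigs.items()],
        "RG": sorted({r.sample_id for r in records}),
    }
    header["RG"] = [{"ID": s, "SM": s} for s in header["RG"]]
    names = list(ref.contigs)
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.reference_id = names.index(r.contig)
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar
            a.is_reverse = r.strand == "-"
            if r.mate_contig is not None:
                a.next_reference_id = names.index(r.mate_contig)
                a.next_reference_start = r.mate_pos or 0
                a.is_paired = True
                a.is_proper_pair = r.is_proper_pair
            if r.insert_size is not None:
                a.template_length = r.insert_size
            a.set_tag("RG", r.sample_id)
            out.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    """Read a SAM/BAM file into alignment records."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            clip_left = clip_right = 0
            aligned = 0
            for op, n in a.cigartuples or []:
                if op == 4:  # soft clip
                    if aligned == 0:
                        clip_left = n
                    else:
                        clip_right = n
                elif op in (0, 7, 8):
                    aligned += n
            sample = a.get_tag("RG") if a.has_tag("RG") else "sample"
            insert = abs(a.template_length) if a.template_length else None
            mate_contig = None
            mate_pos = None
            if a.is_paired and a.next_reference_id >= 0:
                mate_contig = a.header.get_reference_name(a.next_reference_id)
                mate_pos = a.next_reference_start
            out.append(AlignmentRecord(
                sample_id=str(sample), read_id=a.query_name or "read",
                contig=a.reference_name or "", pos=a.reference_start,
                strand="-" if a.is_reverse else "+", aligned_len=aligned,
                clip_left=clip_left, clip_right=clip_right,
                sequence=a.query_sequence, mapq=a.mapping_quality,
                mate_contig=mate_contig, mate_pos=mate_pos,
                insert_size=insert if mate_contig == a.reference_name else None,
                is_proper_pair=a.is_proper_pair))
    return out
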