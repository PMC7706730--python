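"""Contig resolution: replication models, scores, and eccDNA patterns.

The assembled contig of an SV locus is interpreted as the product of a
replication process: a chain of template segments copied in order, each
junction being a template switch where synthesis resumed elsewhere (often
at a microhomologous site).  The chain's coverage arithmetic over the
rearranged reference span yields the elementary events (deletions,
duplications, inversions, insertions), the switch count and jump
distances, and the size spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .assembly import KmerIndex, SegmentAlignment, align_contig, chain_segments
from .config import DEFAULT_CONFIG, PipelineConfig
from .discovery import SvCall
from .genome import ReferenceGenome, revcomp
from .rearrangement import RearrangementModel, model_from_chain
from .simulate import AlignmentRecord


def classify_rearrangement(chain: list[SegmentAlignment], ref: ReferenceGenome,
                           junction_mh: list[int] | None = None,
                           contig_sequence: str = "",
                           anchor_region: tuple[str, int, int] | None = None,
                           ) -> RearrangementModel:
    """Interpret a contig's segment chain as a replication model.

    The outermost chain elements must be the collinear flank alignments on
    the anchor contig; the reference span between them is the anchor
    region.  Deletions are its sub-spans covered zero times by the chain,
    duplications the spans covered twice or more, inversions the
    reverse-orientation local segments, insertions the segments from
    distal loci or other contigs.  A junction where the next segment does
    not continue contiguously is a template switch.
    """
    if not chain:
        raise ValueError("empty chain cannot be classified")
    first, last = chain[0], chain[-1]
    if anchor_region is not None:
        anchor_contig, anchor_start, anchor_end = anchor_region
        interior = [a.segment for a in chain]
    else:
        if len(chain) == 1:
            seg = first.segment
            return model_from_chain(seg.contig, seg.end, seg.end, [],
                                    junction_mh=junction_mh or [],
                                    contig_sequence=contig_sequence)
        if (first.segment.contig != last.segment.contig
                or first.segment.orientation != "forward"
                or last.segment.orientation != "forward"):
            raise ValueError("chain is not anchored by collinear flanks; "
                             "pass anchor_region explicitly")
        anchor_contig = first.segment.contig
        anchor_start = first.segment.end
        anchor_end = last.segment.start
        interior = [a.segment for a in chain[1:-1]]
    return model_from_chain(anchor_contig, anchor_start, anchor_end, interior,
                            junction_mh=junction_mh or [],
                            contig_sequence=contig_sequence)


def resolve_contig(contig_seq: str, ref: ReferenceGenome,
                   index: KmerIndex | None = None,
                   config: PipelineConfig = DEFAULT_CONFIG,
                   ) -> RearrangementModel | None:
    """Full resolution of one contig: align, chain, classify.

    Returns ``None`` when no alignment is found.  A chain covering less
    than ``min_chain_coverage`` of the contig, or one not anchored by
    forward flanks on a single home contig, is reported with
    ``low_confidence=True`` rather than dropped.
    """
    alns = align_contig(contig_seq, ref, index=index, seed_k=config.seed_k,
                        min_identity=config.min_identity)
    if not alns:
        return None
    chain, mh, coverage = chain_segments(
        alns, len(contig_seq), allowed_overlap=config.max_mh,
        min_chain_coverage=config.min_chain_coverage)
    # canonical orientation: if the terminal flanks aligned to the reverse
    # strand, resolve the reverse-complemented contig instead (mirror model)
    if (len(chain) > 1 and chain[0].segment.orientation == "reverse"
            and chain[-1].segment.orientation == "reverse"
            and chain[0].segment.contig == chain[-1].segment.contig):
        model = resolve_contig(revcomp(contig_seq), ref, index=index, config=config)
        if model is not None:
            model.contig_sequence = contig_seq
        return model
    try:
        model = classify_rearrangement(chain, ref, junction_mh=mh,
                                       contig_sequence=contig_seq)
    except ValueError:
        seg0 = chain[0].segment
        model = classify_rearrangement(
            chain, ref, junction_mh=mh, contig_sequence=contig_seq,
            anchor_region=(seg0.contig, seg0.start, seg0.end))
        model.low_confidence = True
    if coverage < config.min_chain_coverage:
        model.low_confidence = True
    return model


def explanation_score(model: RearrangementModel,
                      abnormal_reads: list[AlignmentRecord],
                      config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Fraction of abnormal reads consistent with the reconstructed allele.

    A read is consistent when it aligns end-to-end to the resolved contig
    (either strand) with at most ``max_mismatch`` edits.  Calls whose score
    does not exceed ``score_threshold`` are rejected as unexplained.
    """
    if not abnormal_reads:
        return 0.0
    target = model.contig_sequence
    if not target:
        raise ValueError("model carries no contig sequence")
    n_ok = 0
    for r in abnormal_reads:
        best = min(
            edlib.align(r.sequence, target, mode="HW", task="distance")["editDistance"],
            edlib.align(revcomp(r.sequence), target, mode="HW",
                        task="distance")["editDistance"],
            key=lambda d: d if d >= 0 else 10**9)
        if 0 <= best <= config.max_mismatch:
            n_ok += 1
    return n_ok / len(abnormal_reads)


def passes_explanation(score: float, config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """Strictly-greater rule: a score equal to the threshold is rejected."""
    return score > config.score_threshold


# ---------------------------------------------------------------------------
# eccDNA
# ---------------------------------------------------------------------------

@dataclass
class CircularDnaEvent:
    """A deletion and duplication with reciprocally matching breakpoints,
    interpreted as an extrachromosomal circle excised from the deleted span."""

    contig: str
    start: int
    end: int
    deletion: SvCall
    duplication: SvCall
    junction_mh: int = 0


def detect_eccdna(calls: list[SvCall],
                  config: PipelineConfig = DEFAULT_CONFIG,
                  ) -> tuple[list[CircularDnaEvent], list[SvCall]]:
    """Fuse DEL/DUP pairs with reciprocally matching breakpoints.

    Both breakpoints must coincide within ``cluster_tolerance`` (plus the
    microhomology ambiguity); the fused pair leaves the plain call list.
    """
    tol = config.cluster_tolerance + config.max_mh
    events: list[CircularDnaEvent] = []
    consumed: set[int] = set()
    dels = [(i, c) for i, c in enumerate(calls) if c.sv_type == "DEL"]
    dups = [(i, c) for i, c in enumerate(calls) if c.sv_type == "DUP"]
    for i, d in dels:
        if i in consumed:
            continue
        for j, u in dups:
            if j in consumed or u.contig != d.contig:
                continue
            if abs(u.start - d.start) <= tol and abs(u.end - d.end) <= tol:
                events.append(CircularDnaEvent(
                    d.contig, min(d.start, u.start), max(d.end, u.end), d, u))
                consumed.update((i, j))
                break
    remaining = [c for i, c in enumerate(calls) if i not in consumed]
    return events, remaining
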