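"""Rearrangement arithmetic shared by the simulator and the resolver.

A (complex) structural-variant allele is an ordered chain of oriented
reference segments replacing a reference span (the anchor).  This module
owns the coordinate arithmetic on such chains: which reference bases are
deleted / duplicated, which segments are inverted or inserted from distal
loci, how many replication template switches the chain implies, and the
microhomology operator applied at junctions.  Both the truth generator
(from a declarative allele) and the resolver (from an assembled contig's
segment chain) call into the same definitions, so a round trip is checked
against one arithmetic, derived through two very different paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, Segment

#: a chain segment on the anchor contig further than this from the anchor is
#: treated as a distal insertion rather than part of the rearranged region
LOCAL_SPAN = 10_000


@dataclass(frozen=True)
class RearrangementEvent:
    """One elementary event implied by a segment chain."""

    kind: str          # DEL | DUP | INV | INS
    contig: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int]:
        return (self.kind, self.size)


def segments_contiguous(prev: Segment, nxt: Segment) -> bool:
    """True if ``nxt`` continues ``prev`` collinearly (same contig and
    orientation, zero gap) so that no template switch is needed between them."""
    if prev.contig != nxt.contig or prev.orientation != nxt.orientation:
        return False
    if prev.orientation == "forward":
        return prev.end == nxt.start
    return prev.start == nxt.end


def _donor_breakpoint(seg: Segment) -> int:
    """Genome coordinate where replication leaves the donor template."""
    return seg.end if seg.orientation == "forward" else seg.start


def _acceptor_breakpoint(seg: Segment) -> int:
    """Genome coordinate where replication resumes on the acceptor template."""
    return seg.start if seg.orientation == "forward" else seg.end


def full_chain(anchor_contig: str, anchor_start: int, anchor_end: int,
               chain: list[Segment], contig_length: int) -> list[Segment]:
    """Chain flanked by the collinear anchor flanks (as plain segments)."""
    left = Segment(anchor_contig, max(0, anchor_start - 1), max(1, anchor_start), "forward")
    right = Segment(anchor_contig, anchor_end, min(contig_length, anchor_end + 1), "forward")
    return [left, *chain, right]


def count_template_switches(anchor_contig: str, anchor_start: int, anchor_end: int,
                            chain: list[Segment]) -> tuple[int, list[int | None]]:
    """Template switches and per-switch jump distances for a chain.

    A junction counts as a switch when the next segment does not continue
    contiguously from the previous one; the flank junctions at the anchor
    are included.  Jump distance is the reference distance between the donor
    end and the acceptor start; ``None`` marks an inter-chromosomal jump.
    An empty chain over a non-empty anchor (a pure deletion) is one switch.
    """
    # conceptual flanks: forward templates ending at anchor_start / starting
    # at anchor_end
    points: list[tuple[str, int, str, int]] = []  # (contig, donor_bp, orient, acceptor_bp)
    elems: list[tuple[str, str, int, int]] = [("flankL", anchor_contig, anchor_start, anchor_start)]
    jumps: list[int | None] = []
    n = 0

    prev_contig, prev_orient, prev_donor = anchor_contig, "forward", anchor_start

    def junction(nxt_contig: str, nxt_orient: str, nxt_acceptor: int,
                 contiguous: bool) -> None:
        nonlocal n
        if contiguous:
            return
        n += 1
        if nxt_contig == prev_contig:
            jumps.append(abs(nxt_acceptor - prev_donor))
        else:
            jumps.append(None)

    for seg in chain:
        contiguous = (seg.contig == prev_contig and seg.orientation == prev_orient
                      and _acceptor_breakpoint(seg) == prev_donor)
        junction(seg.contig, seg.orientation, _acceptor_breakpoint(seg), contiguous)
        prev_contig, prev_orient, prev_donor = seg.contig, seg.orientation, _donor_breakpoint(seg)

    contiguous = (prev_contig == anchor_contig and prev_orient == "forward"
                  and anchor_end == prev_donor)
    junction(anchor_contig, "forward", anchor_end, contiguous)
    return n, jumps


def events_from_chain(anchor_contig: str, anchor_start: int, anchor_end: int,
                      chain: list[Segment], local_span: int = LOCAL_SPAN):
    """Elementary events, anchor region and base partition implied by a chain.

    Returns ``(events, region, partition)`` where ``region`` is the
    (contig, start, end) rearranged reference span and ``partition`` the
    dict of its base classes: ``deleted`` (covered by nothing), ``replicated``
    (covered by at least one interior chain segment) and ``collinear``
    (covered only by the anchor flanks).  The three always sum to the region
    length.
    """
    local: list[Segment] = []
    distal: list[Segment] = []
    for seg in chain:
        is_local = (seg.contig == anchor_contig
                    and seg.start <= anchor_end + local_span
                    and seg.end >= anchor_start - local_span)
        (local if is_local else distal).append(seg)

    region_start = min([anchor_start] + [s.start for s in local])
    region_end = max([anchor_end] + [s.end for s in local])
    n = region_end - region_start
    cover = np.zeros(n, dtype=np.int32)
    seg_cover = np.zeros(n, dtype=bool)
    # flank coverage inside the region
    cover[: anchor_start - region_start] += 1
    if region_end > anchor_end:
        cover[anchor_end - region_start:] += 1
    for seg in local:
        cover[seg.start - region_start: seg.end - region_start] += 1
        seg_cover[seg.start - region_start: seg.end - region_start] = True

    events: list[RearrangementEvent] = []
    for kind, mask in (("DEL", cover == 0), ("DUP", cover >= 2)):
        padded = np.concatenate([[False], mask, [False]])
        diff = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(diff[::2], diff[1::2]):
            events.append(RearrangementEvent(kind, anchor_contig,
                                             region_start + int(s), region_start + int(e)))
    for seg in local:
        if seg.is_reverse:
            events.append(RearrangementEvent("INV", seg.contig, seg.start, seg.end))
    for seg in distal:
        events.append(RearrangementEvent("INS", seg.contig, seg.start, seg.end))

    deleted = int((cover == 0).sum())
    replicated = int(seg_cover.sum())
    partition = {"deleted": deleted, "replicated": replicated,
                 "collinear": n - deleted - replicated}
    return events, (anchor_contig, region_start, region_end), partition


def absolute_size(anchor_start: int, anchor_end: int, chain: list[Segment]) -> int:
    """|reference length − alternate length| over the anchor span."""
    return abs((anchor_end - anchor_start) - sum(len(s) for s in chain))


# ---------------------------------------------------------------------------
# microhomology
# ---------------------------------------------------------------------------

def _common_suffix(a: str, b: str, limit: int) -> int:
    m = 0
    while m < limit and m < len(a) and m < len(b) and a[-1 - m] == b[-1 - m]:
        m += 1
    return m


def _common_prefix(a: str, b: str, limit: int) -> int:
    m = 0
    while m < limit and m < len(a) and m < len(b) and a[m] == b[m]:
        m += 1
    return m


def detect_microhomology(donor_left: str, donor_right: str,
                         acceptor_left: str, acceptor_right: str,
                         max_mh: int = 20) -> int:
    """Microhomology length at a junction between two templates.

    ``donor_left``/``donor_right`` are the template bases immediately before
    and after the donor breakpoint (in template orientation); likewise for
    the acceptor.  Left-side homology is the shared suffix of the two left
    flanks, right-side homology the shared prefix of the two right flanks;
    the junction's MH is the larger of the two (the junction placement is
    ambiguous by that many bases).  Truncated flanks simply reduce the
    measurable maximum.
    """
    left = _common_suffix(donor_left, acceptor_left, max_mh)
    right = _common_prefix(donor_right, acceptor_right, max_mh)
    return max(left, right)


def template_flanks(ref: ReferenceGenome, seg: Segment, at_start: bool,
                    width: int) -> tuple[str, str]:
    """(left, right) template-oriented flanks around a segment boundary.

    ``at_start=True`` gives the flanks around the template's first base
    (the acceptor breakpoint); ``at_start=False`` around the position just
    past its last base (the donor breakpoint).  Coordinates outside the
    segment extend into the surrounding reference along the template's
    orientation, truncated at contig ends.
    """
    seq = ref.contigs[seg.contig]
    L = len(seq)
    if seg.orientation == "forward":
        bp = seg.start if at_start else seg.end
        return seq[max(0, bp - width):bp], seq[bp:bp + width]
    # reverse template runs from seg.end-1 down to seg.start
    from .genome import revcomp
    bp = seg.end if at_start else seg.start
    left = revcomp(seq[bp:min(L, bp + width)])
    right = revcomp(seq[max(0, bp - width):bp])
    return left, right


def junction_mh_from_ref(ref: ReferenceGenome, donor: Segment, acceptor: Segment,
                         max_mh: int = 20) -> int:
    """MH operator applied to a donor→acceptor junction on the reference."""
    dl, dr = template_flanks(ref, donor, at_start=False, width=max_mh + 1)
    al, ar = template_flanks(ref, acceptor, at_start=True, width=max_mh + 1)
    return detect_microhomology(dl, dr, al, ar, max_mh)


# ---------------------------------------------------------------------------
# resolved-model container and spectra
# ---------------------------------------------------------------------------

@dataclass
class RearrangementModel:
    """Resolved interpretation of a contig as a replication product."""

    anchor_region: tuple[str, int, int]
    anchor_start: int          # reference span replaced by the chain
    anchor_end: int
    chain: list[Segment]
    events: list[RearrangementEvent]
    template_switches: int
    switch_distances: list[int | None]
    replicated_fragment_sizes: list[int]
    deleted_region_sizes: list[int]
    junction_mh: list[int]
    absolute_size: int
    partition: dict[str, int]
    low_confidence: bool = False
    contig_sequence: str = ""

    @property
    def event_multiset(self) -> list[tuple[str, int]]:
        return sorted(e.key() for e in self.events)


def model_from_chain(anchor_contig: str, anchor_start: int, anchor_end: int,
                     chain: list[Segment], junction_mh: list[int] | None = None,
                     contig_sequence: str = "",
                     local_span: int = LOCAL_SPAN) -> RearrangementModel:
    """Build a :class:`RearrangementModel` from a segment chain."""
    events, region, partition = events_from_chain(
        anchor_contig, anchor_start, anchor_end, chain, local_span)
    switches, jumps = count_template_switches(anchor_contig, anchor_start,
                                              anchor_end, chain)
    return RearrangementModel(
        anchor_region=region,
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        chain=list(chain),
        events=events,
        template_switches=switches,
        switch_distances=jumps,
        replicated_fragment_sizes=[len(s) for s in chain],
        deleted_region_sizes=[e.size for e in events if e.kind == "DEL"],
        junction_mh=list(junction_mh or []),
        absolute_size=absolute_size(anchor_start, anchor_end, chain),
        partition=partition,
        contig_sequence=contig_sequence,
    )


def size_spectra(models: list[RearrangementModel]) -> pd.DataFrame:
    """Long-form table of switch / replicated-fragment / deleted-region sizes."""
    if not models:
        raise ValueError("size_spectra needs at least one resolved model")
    rows = []
    for i, m in enumerate(models):
        for d in m.switch_distances:
            if d is not None:
                rows.append((i, "switch", d))
        for s in m.replicated_fragment_sizes:
            rows.append((i, "replicated_fragment", s))
        for s in m.deleted_region_sizes:
            rows.append((i, "deleted_region", s))
    return pd.DataFrame(rows, columns=["model", "kind", "size"])
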