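"""Declarative SV alleles and their implantation into a reference genome.

An :class:`AltAlleleSpec` describes a (possibly complex) alternate allele as
an ordered chain of oriented reference segments replacing a reference span.
``implant_sv`` realizes the allele: it edits the reference so that every
junction carries exactly the requested microhomology (left-homology
realization, see docs), builds the alternate sequence from the edited
genome, and emits an exact :class:`TruthRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import ReferenceGenome, Segment, revcomp
from .rearrangement import (RearrangementEvent, absolute_size, events_from_chain,
                            detect_microhomology)

_CYCLE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class AltAlleleSpec:
    """A complex SV allele: ``chain`` replaces ``deleted_span`` bases at ``anchor``.

    ``junction_mh`` requests one microhomology length per junction: the
    junction from the left flank into the first segment, each inter-segment
    junction, and the junction from the last segment into the right flank —
    ``len(chain) + 1`` values in total.  Segments may repeat (duplication)
    and may come from any contig (inter-chromosomal insertion).  ``eccdna``
    marks a deletion whose excised span persists as an extrachromosomal
    circle (the simulator then also emits circle-junction reads).
    """

    anchor: tuple[str, int]
    deleted_span: int
    chain: list[Segment]
    junction_mh: list[int]
    label: str
    eccdna: bool = False

    def __post_init__(self) -> None:
        if self.deleted_span < 0:
            raise ValueError("deleted_span must be >= 0")
        if len(self.junction_mh) != len(self.chain) + 1:
            raise ValueError(
                f"junction_mh must have {len(self.chain) + 1} entries, "
                f"got {len(self.junction_mh)}")
        if any(m < 0 for m in self.junction_mh):
            raise ValueError("microhomology lengths must be >= 0")
        if self.eccdna and (self.chain or self.deleted_span <= 0):
            raise ValueError("eccdna alleles must be pure deletions")

    @property
    def anchor_contig(self) -> str:
        return self.anchor[0]

    @property
    def anchor_start(self) -> int:
        return self.anchor[1]

    @property
    def anchor_end(self) -> int:
        return self.anchor[1] + self.deleted_span


@dataclass
class TruthRecord:
    """Ground truth for one implanted allele."""

    label: str
    breakpoints: list[tuple[str, int, str, str, int, str]]
    event_classes: list[RearrangementEvent]
    absolute_size: int
    carrier_clones: list[str] = field(default_factory=list)
    # provenance for round-trip checks and read simulation
    anchor_contig: str = ""
    anchor_start: int = 0
    anchor_end: int = 0
    chain: list[Segment] = field(default_factory=list)
    junction_mh: list[int] = field(default_factory=list)
    region: tuple[str, int, int] = ("", 0, 0)
    eccdna: bool = False

    @property
    def event_multiset(self) -> list[tuple[str, int]]:
        return sorted(e.key() for e in self.event_classes)


class _Editor:
    """Single-base reference edits with contradiction detection."""

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        self.seqs = {name: list(seq) for name, seq in ref.contigs.items()}
        self.ledger: dict[tuple[str, int], str] = {}

    def get(self, contig: str, pos: int) -> str:
        return self.seqs[contig][pos]

    def set(self, contig: str, pos: int, base: str, label: str) -> None:
        if not 0 <= pos < len(self.seqs[contig]):
            raise ValueError(f"{label}: edit position {contig}:{pos} out of bounds")
        key = (contig, pos)
        if key in self.ledger and self.ledger[key] != base:
            raise ValueError(
                f"{label}: contradictory microhomology edits at {contig}:{pos} "
                f"({self.ledger[key]!r} vs {base!r})")
        self.ledger[key] = base
        self.seqs[contig][pos] = base

    def commit(self) -> None:
        for name in self.seqs:
            self.ref.contigs[name] = "".join(self.seqs[name])


class _Template:
    """Oriented template with coordinates relative to one boundary.

    Index 0 is the first base at/after the boundary in template orientation;
    negative indices address bases before it.  Flank templates are modeled
    as forward templates with an open end.
    """

    def __init__(self, contig: str, boundary: int, orientation: str):
        self.contig = contig
        self.boundary = boundary
        self.orientation = orientation

    @classmethod
    def acceptor(cls, seg: Segment) -> "_Template":
        bp = seg.start if seg.orientation == "forward" else seg.end
        return cls(seg.contig, bp, seg.orientation)

    @classmethod
    def donor(cls, seg: Segment) -> "_Template":
        bp = seg.end if seg.orientation == "forward" else seg.start
        return cls(seg.contig, bp, seg.orientation)

    def genome_pos(self, idx: int) -> int:
        if self.orientation == "forward":
            return self.boundary + idx
        return self.boundary - 1 - idx

    def read(self, editor: _Editor, idx: int) -> str:
        b = editor.get(self.contig, self.genome_pos(idx))
        return b if self.orientation == "forward" else _COMP[b]

    def write(self, editor: _Editor, idx: int, base: str, label: str) -> None:
        b = base if self.orientation == "forward" else _COMP[base]
        editor.set(self.contig, self.genome_pos(idx), b, label)


def _contiguous_templates(donor: _Template, acceptor: _Template) -> bool:
    """True when the acceptor continues the donor with zero gap — not a real
    junction, so no microhomology can or need be realized there."""
    return (donor.contig == acceptor.contig
            and donor.orientation == acceptor.orientation
            and donor.boundary == acceptor.boundary)


def _realize_junction(editor: _Editor, donor: _Template, acceptor: _Template,
                      m: int, label: str) -> None:
    """Edit the reference so the junction's measured MH is exactly ``m``.

    Left homology of length ``m`` is created by overwriting the acceptor
    template's ``m`` bases upstream of its breakpoint with the donor's last
    ``m`` bases (these lie outside the alternate sequence).  One extra base
    on each side is forced to differ so neither homology convention extends
    past ``m``.
    """
    if _contiguous_templates(donor, acceptor):
        return
    for i in range(1, m + 1):
        donor_base = donor.read(editor, -i)
        acceptor.write(editor, -i, donor_base, label)
    # stop left homology from extending beyond m
    if _in_bounds(editor, donor, -m - 1) and _in_bounds(editor, acceptor, -m - 1):
        if acceptor.read(editor, -m - 1) == donor.read(editor, -m - 1):
            acceptor.write(editor, -m - 1, _CYCLE[donor.read(editor, -m - 1)], label)
    # kill right homology entirely (the donor base just past its end is
    # outside the alternate sequence and free to edit)
    if _in_bounds(editor, donor, 0) and _in_bounds(editor, acceptor, 0):
        if donor.read(editor, 0) == acceptor.read(editor, 0):
            donor.write(editor, 0, _CYCLE[acceptor.read(editor, 0)], label)


def _in_bounds(editor: _Editor, template: _Template, idx: int) -> bool:
    return 0 <= template.genome_pos(idx) < len(editor.seqs[template.contig])


def _junction_templates(spec: AltAlleleSpec) -> list[tuple[_Template, _Template]]:
    """(donor, acceptor) template pair for every junction of the allele."""
    left_flank = _Template(spec.anchor_contig, spec.anchor_start, "forward")
    right_flank = _Template(spec.anchor_contig, spec.anchor_end, "forward")
    donors = [left_flank] + [_Template.donor(s) for s in spec.chain]
    acceptors = [_Template.acceptor(s) for s in spec.chain] + [right_flank]
    return list(zip(donors, acceptors))


def measure_junction_mh(ref: ReferenceGenome, spec: AltAlleleSpec,
                        max_mh: int = 20) -> list[int]:
    """Apply the MH operator to every junction of an implanted allele."""
    def flanks(t: _Template) -> tuple[str, str]:
        s = ref.contigs[t.contig]
        if t.orientation == "forward":
            return (s[max(0, t.boundary - max_mh - 1):t.boundary],
                    s[t.boundary:t.boundary + max_mh + 1])
        return (revcomp(s[t.boundary:t.boundary + max_mh + 1]),
                revcomp(s[max(0, t.boundary - max_mh - 1):t.boundary]))

    out = []
    for (donor, acceptor), req in zip(_junction_templates(spec),
                                      spec.junction_mh):
        if _contiguous_templates(donor, acceptor):
            # no junction exists here; report the request unchanged
            out.append(req)
            continue
        dl, dr = flanks(donor)
        al, ar = flanks(acceptor)
        out.append(detect_microhomology(dl, dr, al, ar, max_mh))
    return out


def build_alt_sequence(ref: ReferenceGenome, spec: AltAlleleSpec) -> str:
    """Alternate sequence of the allele (chain segments only)."""
    return "".join(ref.fetch(seg) for seg in spec.chain)


def implant_sv(ref: ReferenceGenome, spec: AltAlleleSpec,
               max_mh: int = 20) -> tuple[str, TruthRecord]:
    """Implant an allele: edit ``ref`` in place to realize junction MH and
    return ``(alt_sequence, truth)``.

    The reference is edited *before* any read simulation so genome and reads
    stay self-consistent; every junction is then re-measured with the MH
    operator and the implant is rejected with a diagnostic if overlapping
    edits contradict a requested length.
    """
    contig_len = ref.length(spec.anchor_contig)
    if not 0 <= spec.anchor_start <= spec.anchor_end <= contig_len:
        raise ValueError(f"{spec.label}: anchor span out of bounds")
    for seg in spec.chain:
        if seg.end > ref.length(seg.contig):
            raise ValueError(f"{spec.label}: segment {seg} out of bounds")
    if not spec.chain and spec.deleted_span == 0:
        raise ValueError(f"{spec.label}: allele changes nothing")
    if not spec.chain and spec.junction_mh[0] > spec.deleted_span:
        raise ValueError(f"{spec.label}: requested MH exceeds deleted span")

    editor = _Editor(ref)
    for (donor, acceptor), m in zip(_junction_templates(spec), spec.junction_mh):
        _realize_junction(editor, donor, acceptor, m, spec.label)
    editor.commit()

    # junction boundaries must stay unambiguous: a germline SNP right at a
    # breakpoint would blur the truth coordinates, so the panels are pruned
    # around every junction
    guard: set[tuple[str, int]] = set()
    for (donor, acceptor), m in zip(_junction_templates(spec), spec.junction_mh):
        for t in (donor, acceptor):
            for i in range(-(m + 8), m + 9):
                guard.add((t.contig, t.genome_pos(i)))
    ref.het_snp_sites = [s for s in ref.het_snp_sites if (s[0], s[1]) not in guard]
    ref.hom_snp_sites = [s for s in ref.hom_snp_sites if (s[0], s[1]) not in guard]

    measured = measure_junction_mh(ref, spec, max_mh)
    if measured != list(spec.junction_mh):
        raise ValueError(
            f"{spec.label}: overlapping edits contradict requested microhomology "
            f"(requested {spec.junction_mh}, measured {measured})")

    alt = build_alt_sequence(ref, spec)
    return alt, make_truth_record(spec)


def make_truth_record(spec: AltAlleleSpec) -> TruthRecord:
    """Exact truth twin of an allele spec (no genome access needed)."""
    events, region, _partition = events_from_chain(
        spec.anchor_contig, spec.anchor_start, spec.anchor_end, spec.chain)
    breakpoints = []
    for donor, acceptor in _junction_templates(spec):
        breakpoints.append((
            donor.contig, donor.boundary,
            "+" if donor.orientation == "forward" else "-",
            acceptor.contig, acceptor.boundary,
            "+" if acceptor.orientation == "forward" else "-",
        ))
    return TruthRecord(
        label=spec.label,
        breakpoints=breakpoints,
        event_classes=events,
        absolute_size=absolute_size(spec.anchor_start, spec.anchor_end, spec.chain),
        anchor_contig=spec.anchor_contig,
        anchor_start=spec.anchor_start,
        anchor_end=spec.anchor_end,
        chain=list(spec.chain),
        junction_mh=list(spec.junction_mh),
        region=region,
        eccdna=spec.eccdna,
    )


def implant_all(ref: ReferenceGenome, specs: list[AltAlleleSpec]) -> dict[str, TruthRecord]:
    """Implant several alleles into one genome; returns label -> truth."""
    out: dict[str, TruthRecord] = {}
    for spec in specs:
        _alt, truth = implant_sv(ref, spec)
        out[spec.label] = truth
    return out
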