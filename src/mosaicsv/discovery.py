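"""Breakpoint discovery and clone-to-clone somatic filtering.

Candidates come from split (soft-clipped) and discordant reads; clipped
sequences are cross-matched against partner loci to type deletions, tandem
duplications and inversions, with unpaired candidates reported as breakends
(BND).  Somatic status is established by comparing every clone against
every other clone: a call is voted somatic in a comparison when the control
clone shows no supporting abnormal read at the breakpoints, and calls
consistently voted across comparisons are retained as mosaic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median_low

import edlib
import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .genome import ReferenceGenome, revcomp
from .simulate import AlignmentRecord

log = logging.getLogger("mosaicsv.discovery")


@dataclass
class InsertStats:
    mean: float
    sd: float


def estimate_insert_stats(records: list[AlignmentRecord],
                          min_pairs: int = 100) -> InsertStats:
    """Insert-size mean/SD from properly paired reads."""
    sizes = [r.insert_size for r in records
             if r.is_proper_pair and r.insert_size is not None]
    if len(sizes) < min_pairs:
        raise ValueError(
            f"only {len(sizes)} proper pairs; supply insert statistics explicitly")
    arr = np.asarray(sizes, dtype=float)
    return InsertStats(mean=float(arr.mean()), sd=float(arr.std()))


def extract_abnormal_reads(records: list[AlignmentRecord],
                           locus: tuple[str, int, int] | None = None,
                           config: PipelineConfig = DEFAULT_CONFIG,
                           insert_stats: InsertStats | None = None,
                           ) -> list[AlignmentRecord]:
    """Reads that are soft-clipped by more than ``soft_clip_min`` bases,
    discordant by insert size (mean + k*SD), or have an inter-contig mate.

    With ``locus`` given, restricted to a ±window neighborhood of its ends.
    """
    if insert_stats is None:
        insert_stats = estimate_insert_stats(records)
    cutoff = insert_stats.mean + config.discordance_sds * insert_stats.sd
    out = []
    for r in records:
        abnormal = (r.max_clip > config.soft_clip_min
                    or (r.insert_size is not None and r.insert_size > cutoff)
                    or (r.mate_contig is not None and r.mate_contig != r.contig))
        if not abnormal:
            continue
        if locus is not None:
            contig, start, end = locus
            w = config.window
            if r.contig != contig or not (
                    (start - w <= r.pos <= start + w)
                    or (end - w <= r.end <= end + w)
                    or (start - w <= r.end and r.pos <= end + w)):
                continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class BreakpointCandidate:
    """A clustered soft-clip position (one side of a putative junction)."""

    contig: str
    pos: int
    side: str                      # 'right': clip after pos; 'left': clip before pos
    split_support: int
    discordant_support: int = 0
    samples_with_support: set[str] = field(default_factory=set)
    clip_consensus: str = ""       # longest clipped sequence in the cluster
    reads: list[AlignmentRecord] = field(default_factory=list)


def cluster_breakpoints(abnormal: list[AlignmentRecord],
                        config: PipelineConfig = DEFAULT_CONFIG,
                        ) -> list[BreakpointCandidate]:
    """Merge soft-clip positions within ``cluster_tolerance`` per contig/side.

    Candidate position is the median clip position (lower coordinate on
    ties); discordant pairs are attached to the nearest compatible
    candidate; clusters with fewer than ``min_split_support`` split reads
    are dropped.
    """
    by_key: dict[tuple[str, str], list[tuple[int, AlignmentRecord, str]]] = {}
    discordant: list[AlignmentRecord] = []
    for r in abnormal:
        clipped = False
        if r.clip_right > config.soft_clip_min:
            by_key.setdefault((r.contig, "right"), []).append(
                (r.end, r, r.clipped_right_seq))
            clipped = True
        if r.clip_left > config.soft_clip_min:
            by_key.setdefault((r.contig, "left"), []).append(
                (r.pos, r, r.clipped_left_seq))
            clipped = True
        if not clipped:
            discordant.append(r)

    candidates: list[BreakpointCandidate] = []
    for (contig, side), items in sorted(by_key.items()):
        items.sort(key=lambda t: t[0])
        cluster: list[tuple[int, AlignmentRecord, str]] = []
        for item in items:
            if cluster and item[0] - cluster[-1][0] > config.cluster_tolerance:
                candidates.append(_finish_cluster(contig, side, cluster))
                cluster = []
            cluster.append(item)
        if cluster:
            candidates.append(_finish_cluster(contig, side, cluster))

    candidates = [c for c in candidates if c.split_support >= config.min_split_support]

    for r in discordant:
        best = None
        for c in candidates:
            if c.contig != r.contig:
                continue
            d = min(abs(c.pos - r.pos), abs(c.pos - r.end))
            if d <= config.window and (best is None or d < best[0]):
                best = (d, c)
        if best:
            best[1].discordant_support += 1
            best[1].samples_with_support.add(r.sample_id)
    return candidates


def _finish_cluster(contig: str, side: str,
                    cluster: list[tuple[int, AlignmentRecord, str]]) -> BreakpointCandidate:
    positions = [p for p, _r, _s in cluster]
    pos = median_low(positions)
    consensus = max((s for _p, _r, s in cluster), key=len)
    return BreakpointCandidate(
        contig=contig, pos=pos, side=side, split_support=len(cluster),
        samples_with_support={r.sample_id for _p, r, _s in cluster},
        clip_consensus=consensus, reads=[r for _p, r, _s in cluster])


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------

@dataclass
class SvCall:
    """A discovered breakpoint-level event."""

    sv_type: str                   # DEL | DUP | INV | BND | INS
    sample_id: str
    contig: str
    start: int
    end: int                       # == start for one-sided BND
    breakpoints: list[tuple[str, int, str]]
    split_support: int
    discordant_support: int = 0
    inverted: bool = False         # BND whose clip matches the reverse strand
    one_sided: bool = False
    comparison_votes: int = 0
    informative_comparisons: int = 0
    carriers: list[str] = field(default_factory=list)
    group_id: int | None = None
    mda_artifact: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start

    def locus_key(self) -> tuple[str, str, int]:
        return (self.sv_type, self.contig, self.start)


def _identity_match(seq: str, target: str, min_identity: float) -> bool:
    if not seq or not target:
        return False
    res = edlib.align(seq, target, mode="HW", task="distance")
    return res["editDistance"] >= 0 and 1 - res["editDistance"] / len(seq) >= min_identity


def _clip_continues(ref: ReferenceGenome, seq: str, contig: str, pos: int,
                    direction: str, strand: str, config: PipelineConfig,
                    slack: int | None = None) -> bool:
    """Does a clipped sequence match the reference at the partner locus?

    ``direction='from'``: the sequence continues forward from ``pos``;
    ``direction='to'``: the sequence ends at ``pos``.  ``strand='-'``
    matches against the reverse complement.
    """
    if slack is None:
        slack = config.cluster_tolerance + config.max_mh
    n = len(seq)
    s = ref.contigs[contig]
    if strand == "+":
        if direction == "from":
            target = s[max(0, pos - slack):pos + n + slack]
        else:
            target = s[max(0, pos - n - slack):pos + slack]
    else:
        if direction == "from":
            # reverse-strand continuation starting at pos and moving left
            target = revcomp(s[max(0, pos - n - slack):pos + slack])
        else:
            target = revcomp(s[max(0, pos - slack):pos + n + slack])
    return _identity_match(seq, target, config.clip_match_identity)


def pair_and_type(candidates: list[BreakpointCandidate], ref: ReferenceGenome,
                  sample_id: str = "",
                  config: PipelineConfig = DEFAULT_CONFIG) -> list[SvCall]:
    """Join candidates with reciprocal orientations into typed calls.

    Canonical same-contig signatures (positions a < b): right-clip at a with
    left-clip at b and cross-matching clipped sequences → DEL; left-clip at
    a with right-clip at b → tandem DUP; two same-side clips → INV.
    Inter-contig pairs and unpaired candidates become BNDs; an unpaired
    candidate whose clipped sequence matches the local reverse strand is an
    inverted (one-sided) breakend.
    """
    used = [False] * len(candidates)
    calls: list[SvCall] = []
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i].contig,
                                                          candidates[i].pos))
    for ii, i in enumerate(order):
        if used[i]:
            continue
        A = candidates[i]
        for j in order[ii + 1:]:
            if used[j] or used[i]:
                continue
            B = candidates[j]
            if A.contig != B.contig:
                if (_clip_continues(ref, A.clip_consensus, B.contig, B.pos, "from", "+", config)
                        or _clip_continues(ref, B.clip_consensus, A.contig, A.pos, "to", "+", config)):
                    used[i] = used[j] = True
                    calls.append(SvCall(
                        "BND", sample_id, A.contig, A.pos, A.pos,
                        [(A.contig, A.pos, A.side), (B.contig, B.pos, B.side)],
                        A.split_support + B.split_support,
                        A.discordant_support + B.discordant_support))
                continue
            a, b = A.pos, B.pos
            if A.side == "right" and B.side == "left" and a <= b:
                if (_clip_continues(ref, A.clip_consensus, B.contig, b, "from", "+", config)
                        or _clip_continues(ref, B.clip_consensus, A.contig, a, "to", "+", config)):
                    used[i] = used[j] = True
                    calls.append(SvCall(
                        "DEL", sample_id, A.contig, a, b,
                        [(A.contig, a, "right"), (B.contig, b, "left")],
                        A.split_support + B.split_support,
                        A.discordant_support + B.discordant_support))
            elif A.side == "left" and B.side == "right" and a <= b:
                if (_clip_continues(ref, B.clip_consensus, A.contig, a, "from", "+", config)
                        or _clip_continues(ref, A.clip_consensus, B.contig, b, "to", "+", config)):
                    used[i] = used[j] = True
                    calls.append(SvCall(
                        "DUP", sample_id, A.contig, a, b,
                        [(A.contig, a, "left"), (B.contig, b, "right")],
                        A.split_support + B.split_support,
                        A.discordant_support + B.discordant_support))
            elif A.side == B.side:
                if A.side == "right":
                    ok = (_clip_continues(ref, A.clip_consensus, B.contig, b, "from", "-", config)
                          or _clip_continues(ref, B.clip_consensus, A.contig, a, "from", "-", config))
                else:
                    ok = (_clip_continues(ref, A.clip_consensus, B.contig, b, "to", "-", config)
                          or _clip_continues(ref, B.clip_consensus, A.contig, a, "to", "-", config))
                if ok:
                    used[i] = used[j] = True
                    calls.append(SvCall(
                        "INV", sample_id, A.contig, min(a, b), max(a, b),
                        [(A.contig, a, A.side), (B.contig, b, B.side)],
                        A.split_support + B.split_support,
                        A.discordant_support + B.discordant_support))

    for i, c in enumerate(candidates):
        if used[i]:
            continue
        rescued = _rescue_one_sided(c, ref, sample_id, config)
        if rescued is not None:
            calls.append(rescued)
            continue
        # a fold-back (inverted) continuation may re-prime up to the
        # adjacency distance away, so the reverse-strand search is wide
        if c.side == "right":
            inverted = _clip_continues(ref, c.clip_consensus, c.contig, c.pos,
                                       "from", "-", config,
                                       slack=config.adjacency)
        else:
            inverted = _clip_continues(ref, c.clip_consensus, c.contig, c.pos,
                                       "to", "-", config,
                                       slack=config.adjacency)
        calls.append(SvCall(
            "BND", sample_id, c.contig, c.pos, c.pos,
            [(c.contig, c.pos, c.side)], c.split_support, c.discordant_support,
            inverted=inverted, one_sided=True))
    return calls


def _rescue_one_sided(c: BreakpointCandidate, ref: ReferenceGenome,
                      sample_id: str, config: PipelineConfig) -> SvCall | None:
    """Type an unpaired candidate by locating its clipped sequence nearby.

    A right-clip whose clipped tail matches the forward reference ahead of
    the clip is a deletion junction (the partner side merely lacked split
    support); a match behind the clip is a tandem-duplication junction.
    The mirror logic applies to left-clips.  The search spans
    ``rescue_span`` bases and requires the usual clipped-sequence identity.
    """
    s = c.clip_consensus
    if len(s) < config.soft_clip_min:
        return None
    span = config.rescue_span
    seq = ref.contigs[c.contig]
    max_dist = int((1 - config.clip_match_identity) * len(s))

    def best(target: str):
        if len(target) < len(s):
            return None
        res = edlib.align(s, target, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > max_dist:
            return None
        return res["editDistance"], res["locations"][0]

    p = c.pos
    if c.side == "right":
        ahead = best(seq[p + 1:p + span])          # DEL: continues at b > p
        behind = best(seq[max(0, p - span):p])     # DUP: continues at a < p
        if ahead is not None and (behind is None or ahead[0] <= behind[0]):
            b = p + 1 + ahead[1][0]
            return SvCall("DEL", sample_id, c.contig, p, b,
                          [(c.contig, p, "right"), (c.contig, b, "left")],
                          c.split_support, c.discordant_support)
        if behind is not None:
            a = max(0, p - span) + behind[1][0]
            return SvCall("DUP", sample_id, c.contig, a, p,
                          [(c.contig, a, "left"), (c.contig, p, "right")],
                          c.split_support, c.discordant_support)
    else:
        behind = best(seq[max(0, p - span):p - 1 if p > 0 else 0])  # DEL: ends at a < p
        ahead = best(seq[p:p + span])                               # DUP: ends at b > p
        if behind is not None and (ahead is None or behind[0] <= ahead[0]):
            a = max(0, p - span) + behind[1][1] + 1
            if a < p:
                return SvCall("DEL", sample_id, c.contig, a, p,
                              [(c.contig, a, "right"), (c.contig, p, "left")],
                              c.split_support, c.discordant_support)
        if ahead is not None:
            b = p + ahead[1][1] + 1
            return SvCall("DUP", sample_id, c.contig, p, b,
                          [(c.contig, p, "left"), (c.contig, b, "right")],
                          c.split_support, c.discordant_support)
    return None


# ---------------------------------------------------------------------------
# clone-to-clone somatic filtering
# ---------------------------------------------------------------------------

def _control_supports(call: SvCall, control: list[AlignmentRecord],
                      config: PipelineConfig) -> int:
    """Number of control abnormal reads supporting the call's breakpoints."""
    n = 0
    for r in control:
        for contig, pos, side in call.breakpoints:
            if r.contig != contig:
                continue
            if (side == "right" and r.clip_right > config.soft_clip_min
                    and abs(r.end - pos) <= config.cluster_tolerance):
                n += 1
            elif (side == "left" and r.clip_left > config.soft_clip_min
                    and abs(r.pos - pos) <= config.cluster_tolerance):
                n += 1
    return n


def call_somatic_pairwise(case_calls: list[SvCall],
                          controls: dict[str, list[AlignmentRecord]],
                          config: PipelineConfig = DEFAULT_CONFIG) -> list[SvCall]:
    """Vote each case call somatic against every control clone.

    A comparison votes somatic iff the control shows zero supporting
    abnormal reads at the call's breakpoints.  Votes accumulate on the
    call; the number of informative comparisons is recorded alongside.
    """
    for call in case_calls:
        call.comparison_votes = 0
        call.informative_comparisons = 0
        for control_id, records in controls.items():
            if control_id == call.sample_id:
                continue
            call.informative_comparisons += 1
            if _control_supports(call, records, config) == 0:
                call.comparison_votes += 1
    return case_calls


def recurrence_filter(calls_by_clone: dict[str, list[SvCall]],
                      config: PipelineConfig = DEFAULT_CONFIG) -> list[SvCall]:
    """Retain calls consistently voted somatic across comparisons.

    Calls from different clones at the same locus are first matched (same
    type, breakpoints within tolerance or 50% reciprocal overlap), so a
    shared SV is reported once with its carrier list.  Each carrier must be
    voted somatic in at least ``recurrence_fraction`` of its informative
    non-carrier comparisons.
    """
    flat: list[SvCall] = [c for calls in calls_by_clone.values() for c in calls]
    groups: list[list[SvCall]] = []
    for call in flat:
        for g in groups:
            if _same_locus(call, g[0], config):
                g.append(call)
                break
        else:
            groups.append([call])

    retained: list[SvCall] = []
    for g in groups:
        carriers = sorted({c.sample_id for c in g})
        ok = True
        for c in g:
            non_carrier = c.informative_comparisons - (len(carriers) - 1)
            if non_carrier <= 0:
                ok = False
                break
            # votes against carrier controls cannot occur (they share the
            # signal), so votes are effectively counted among non-carriers
            if c.comparison_votes < config.recurrence_fraction * non_carrier:
                ok = False
                break
        if not ok:
            log.info("recurrence_filter removed %s at %s:%d-%d",
                     g[0].sv_type, g[0].contig, g[0].start, g[0].end)
            continue
        rep = max(g, key=lambda c: c.split_support)
        rep.carriers = carriers
        retained.append(rep)
    return retained


def _same_locus(a: SvCall, b: SvCall, config: PipelineConfig) -> bool:
    if a.sv_type != b.sv_type or a.contig != b.contig:
        return False
    tol = config.cluster_tolerance + config.max_mh
    if abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol:
        return True
    if a.span > 0 and b.span > 0:
        ov = min(a.end, b.end) - max(a.start, b.start)
        return ov >= config.reciprocal_overlap * max(a.span, b.span) > 0
    return False


# ---------------------------------------------------------------------------
# merging, grouping, artifact and catalog filters
# ---------------------------------------------------------------------------

def merge_reciprocal(calls: list[SvCall],
                     config: PipelineConfig = DEFAULT_CONFIG) -> list[SvCall]:
    """Merge same-type calls whose spans overlap reciprocally.

    Two calls merge when the overlap is at least ``reciprocal_overlap`` of
    BOTH span lengths; the merged span is the union and supports are
    summed.  Applied to a fixpoint, so the operation is idempotent.
    """
    calls = list(calls)
    changed = True
    while changed:
        changed = False
        out: list[SvCall] = []
        for call in sorted(calls, key=lambda c: (c.contig, c.start, c.end)):
            merged = False
            for prev in out:
                if prev.sv_type != call.sv_type or prev.contig != call.contig:
                    continue
                if prev.span == 0 or call.span == 0:
                    continue
                ov = min(prev.end, call.end) - max(prev.start, call.start)
                if ov >= config.reciprocal_overlap * max(prev.span, call.span):
                    prev.start = min(prev.start, call.start)
                    prev.end = max(prev.end, call.end)
                    prev.split_support += call.split_support
                    prev.discordant_support += call.discordant_support
                    prev.breakpoints = prev.breakpoints + call.breakpoints
                    merged = changed = True
                    break
            if not merged:
                out.append(call)
        calls = out
    return calls


def group_adjacent_complex(calls: list[SvCall],
                           config: PipelineConfig = DEFAULT_CONFIG,
                           ) -> list[list[SvCall]]:
    """Single-linkage grouping of same-sample calls with breakpoints within
    ``adjacency`` bp; groups of two or more events form a complex SV.

    Every call lands in exactly one group (a partition).
    """
    n = len(calls)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if a.sample_id != b.sample_id:
                continue
            close = any(
                ca == cb and abs(pa - pb) <= config.adjacency
                for ca, pa, _sa in a.breakpoints
                for cb, pb, _sb in b.breakpoints)
            if close:
                union(i, j)

    groups: dict[int, list[SvCall]] = {}
    for i, call in enumerate(calls):
        groups.setdefault(find(i), []).append(call)
    out = []
    for gid, group in enumerate(groups.values()):
        for c in group:
            c.group_id = gid
        out.append(sorted(group, key=lambda c: (c.contig, c.start)))
    return out


def flag_mda_artifacts(groups: list[list[SvCall]],
                       config: PipelineConfig = DEFAULT_CONFIG) -> list[bool]:
    """Flag groups that look like MDA chimera artifacts.

    A group is flagged iff it contains an unpaired inverted breakend
    adjacent to a duplication (the displaced-strand re-priming pattern) —
    fully reciprocal DEL+DUP pairs (the eccDNA pattern) are not flagged.
    """
    flags = []
    for group in groups:
        bnds = [c for c in group if c.sv_type == "BND" and c.one_sided and c.inverted]
        dups = [c for c in group if c.sv_type == "DUP"]
        flagged = False
        for bnd in bnds:
            for dup in dups:
                if bnd.contig == dup.contig and (
                        min(abs(bnd.start - dup.start), abs(bnd.start - dup.end))
                        <= config.adjacency):
                    flagged = True
        for c in group:
            c.mda_artifact = c.mda_artifact or flagged
        flags.append(flagged)
    return flags


def filter_known_germline(calls: list[SvCall],
                          catalog: list[tuple[str, int, int]],
                          config: PipelineConfig = DEFAULT_CONFIG) -> list[SvCall]:
    """Remove calls reciprocally overlapping a germline-catalog interval."""
    for contig, start, end in catalog:
        if not isinstance(start, int) or not isinstance(end, int) or start >= end:
            raise ValueError(f"malformed catalog interval {contig}:{start}-{end}")
    kept = []
    for call in calls:
        removed = False
        for contig, start, end in catalog:
            if call.contig != contig or call.span == 0:
                continue
            ov = min(call.end, end) - max(call.start, start)
            if ov >= config.reciprocal_overlap * max(call.span, end - start):
                log.info("germline catalog removed %s at %s:%d-%d",
                         call.sv_type, call.contig, call.start, call.end)
                removed = True
                break
        if not removed:
            kept.append(call)
    return kept


def read_bed(path) -> list[tuple[str, int, int]]:
    """Minimal BED reader (contig, start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as e:
                raise ValueError(f"malformed BED line: {line!r}") from e
    return out
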