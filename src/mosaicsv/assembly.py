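"""Local assembly of abnormal reads and contig-to-reference alignment.

Assembly is greedy overlap-layout-consensus: the read pool at one SV locus
is tiny (tens of reads), so repeatedly merging the pair with the longest
near-exact suffix/prefix overlap is simple, fast and deterministic.
Contigs are then aligned to the reference by exact k-mer seeding on both
strands followed by maximal exact extension, and the best tiling of the
contig by reference segments is selected by weighted interval scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import ReferenceGenome, Segment, revcomp


@dataclass
class Contig:
    """An assembled consensus sequence with per-base read support."""

    sequence: str
    read_ids: list[str]
    depth: list[int]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SegmentAlignment:
    """A local alignment of a contig interval to an oriented reference segment."""

    contig_start: int
    contig_end: int
    segment: Segment
    identity: float

    def __post_init__(self) -> None:
        if self.contig_end - self.contig_start != len(self.segment):
            raise ValueError("contig interval and segment lengths differ")

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start

    @property
    def weight(self) -> float:
        return self.length * self.identity


# ---------------------------------------------------------------------------
# greedy OLC assembly
# ---------------------------------------------------------------------------

def _overlap_candidates(a: str, b: str, k: int) -> set[int]:
    """Candidate suffix(a)/prefix(b) overlap lengths from shared k-mers."""
    if len(a) < k or len(b) < k:
        return set()
    index: dict[str, list[int]] = {}
    # k-mers of b's prefix region
    for pb in range(len(b) - k + 1):
        index.setdefault(b[pb:pb + k], []).append(pb)
    lengths: set[int] = set()
    for pa in range(len(a) - k + 1):
        for pb in index.get(a[pa:pa + k], ()):
            L = len(a) - pa + pb
            if 0 < L <= min(len(a), len(b)):
                lengths.add(L)
    return lengths


def _check_overlap(a: str, b: str, L: int, max_mismatch: int) -> bool:
    mm = 0
    sa = a[len(a) - L:]
    sb = b[:L]
    for x, y in zip(sa, sb):
        if x != y:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


class _Piece:
    __slots__ = ("seq", "depth", "read_ids")

    def __init__(self, seq: str, depth: list[int], read_ids: list[str]):
        self.seq = seq
        self.depth = depth
        self.read_ids = read_ids

    def rc(self) -> "_Piece":
        return _Piece(revcomp(self.seq), self.depth[::-1], self.read_ids)


def _merge(a: _Piece, b: _Piece, L: int) -> _Piece:
    """Merge a's suffix with b's prefix over overlap L; mismatch columns take
    the base with higher read support (lexicographically smaller on ties)."""
    head = a.seq[:len(a.seq) - L]
    ov = []
    for i in range(L):
        xa, xb = a.seq[len(a.seq) - L + i], b.seq[i]
        if xa == xb:
            ov.append(xa)
        else:
            da, db = a.depth[len(a.seq) - L + i], b.depth[i]
            if da > db:
                ov.append(xa)
            elif db > da:
                ov.append(xb)
            else:
                ov.append(min(xa, xb))
    tail = b.seq[L:]
    depth = (a.depth[:len(a.seq) - L]
             + [a.depth[len(a.seq) - L + i] + b.depth[i] for i in range(L)]
             + b.depth[L:])
    return _Piece(head + "".join(ov) + tail, depth, a.read_ids + b.read_ids)


def assemble_contigs(reads, min_overlap: int = 20,
                     max_mismatch: int = 2) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly of a small read set.

    ``reads`` is a list of sequences or (read_id, sequence) pairs; both
    orientations are considered when searching overlaps.  The pair with the
    longest overlap is merged first; ties break toward the lexicographically
    smallest merged sequence, making the result deterministic.  Reads with
    no overlap remain as single-read contigs.
    """
    items: list[tuple[str, str]] = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            items.append((f"read{i}", r))
        else:
            items.append((r[0], r[1]))
    # deduplicate exact sequences, accumulating depth
    seen: dict[str, _Piece] = {}
    for rid, seq in items:
        if not seq:
            continue
        if seq in seen:
            p = seen[seq]
            p.depth = [d + 1 for d in p.depth]
            p.read_ids.append(rid)
        elif revcomp(seq) in seen:
            p = seen[revcomp(seq)]
            p.depth = [d + 1 for d in p.depth]
            p.read_ids.append(rid)
        else:
            seen[seq] = _Piece(seq, [1] * len(seq), [rid])
    pieces = sorted(seen.values(), key=lambda p: p.seq)

    # candidate overlaps come from shared k-mers: k at half the minimum
    # overlap keeps one exact seed on either side of an isolated error
    k = max(4, min(min_overlap // 2, 12))
    while len(pieces) > 1:
        best: tuple[int, str, int, int, bool] | None = None  # (L, merged_seq, i, j, rc)
        for i in range(len(pieces)):
            for j in range(len(pieces)):
                if i == j:
                    continue
                for flip in (False, True):
                    b = pieces[j].rc() if flip else pieces[j]
                    for L in sorted(_overlap_candidates(pieces[i].seq, b.seq, k),
                                    reverse=True):
                        if L < min_overlap or (best is not None and L < best[0]):
                            break
                        if not _check_overlap(pieces[i].seq, b.seq, L, max_mismatch):
                            continue
                        merged_seq = pieces[i].seq[:len(pieces[i].seq) - L] + b.seq
                        if (best is None or L > best[0]
                                or (L == best[0] and merged_seq < best[1])):
                            best = (L, merged_seq, i, j, flip)
                        break  # largest valid overlap for this pair found
        if best is None:
            break
        L, _seq, i, j, flip = best
        b = pieces[j].rc() if flip else pieces[j]
        merged = _merge(pieces[i], b, L)
        pieces = [p for idx, p in enumerate(pieces) if idx not in (i, j)]
        pieces.append(merged)
        pieces.sort(key=lambda p: p.seq)

    return [Contig(p.seq, p.read_ids, p.depth)
            for p in sorted(pieces, key=lambda p: (-len(p.seq), p.seq))]


# ---------------------------------------------------------------------------
# contig alignment
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer index over a reference genome (forward strand)."""

    def __init__(self, ref: ReferenceGenome, k: int = 15):
        self.ref = ref
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in ref.contigs.items():
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos:pos + k], []).append((contig, pos))

    def hits(self, kmer: str):
        return self.index.get(kmer, ())


def _extend_run(query: str, ref_seq: str, q0: int, q1: int, r0: int,
                confirm: int = 5, max_mm: int = 10) -> tuple[int, int, int, int]:
    """Maximal extension of a matching run on a fixed diagonal.

    Isolated mismatches (sequencing errors) are crossed only when the next
    ``confirm`` bases all match — a junction's continuation is random
    sequence, so extension cannot creep past the breakpoint and junction
    boundaries stay exact.  Returns (q0, q1, r0, mismatches).
    """
    mm = 0

    def confirmed(qi: int, ri: int, step: int) -> bool:
        for k in range(1, confirm + 1):
            qq, rr = qi + step * k, ri + step * k
            if not (0 <= qq < len(query) and 0 <= rr < len(ref_seq)):
                return False
            if query[qq] != ref_seq[rr]:
                return False
        return True

    while q0 > 0 and r0 > 0:
        if query[q0 - 1] == ref_seq[r0 - 1]:
            q0 -= 1
            r0 -= 1
        elif mm < max_mm and confirmed(q0 - 1, r0 - 1, -1):
            mm += 1
            q0 -= 1
            r0 -= 1
        else:
            break
    r1 = r0 + (q1 - q0)
    while q1 < len(query) and r1 < len(ref_seq):
        if query[q1] == ref_seq[r1]:
            q1 += 1
            r1 += 1
        elif mm < max_mm and confirmed(q1, r1, +1):
            mm += 1
            q1 += 1
            r1 += 1
        else:
            break
    return q0, q1, r0, mm


def _strand_alignments(query: str, idx: KmerIndex,
                       min_len: int) -> list[tuple[int, int, str, int, int]]:
    """Maximal runs (q0, q1, ref_contig, r0, mismatches) for a query string."""
    k = idx.k
    diagonals: dict[tuple[str, int], list[int]] = {}
    for q in range(0, len(query) - k + 1):
        for contig, r in idx.hits(query[q:q + k]):
            diagonals.setdefault((contig, r - q), []).append(q)
    runs: set[tuple[int, int, str, int, int]] = set()
    for (contig, diag), qs in diagonals.items():
        ref_seq = idx.ref.contigs[contig]
        qs.sort()
        covered_to = -1
        for q in qs:
            if q < covered_to:
                continue
            q0, q1, r0, mm = _extend_run(query, ref_seq, q, q + k, q + diag)
            covered_to = q1
            if q1 - q0 >= min_len:
                runs.add((q0, q1, contig, r0, mm))
    return sorted(runs)


def align_contig(contig_seq: str, ref: ReferenceGenome,
                 index: KmerIndex | None = None, seed_k: int = 15,
                 min_identity: float = 0.9, min_len: int = 20) -> list[SegmentAlignment]:
    """All maximal local alignments of a contig to the reference.

    Exact k-mer seeds are grouped per diagonal and extended maximally on
    both strands; every run of at least ``min_len`` bases is reported.  An
    empty list means the contig could not be placed (the resolver then
    reports the locus unresolved).
    """
    if len(contig_seq) < seed_k:
        raise ValueError("contig shorter than seed_k")
    if index is None or index.k != seed_k:
        index = KmerIndex(ref, seed_k)
    out: list[SegmentAlignment] = []
    n = len(contig_seq)
    for q0, q1, contig, r0, mm in _strand_alignments(contig_seq, index, min_len):
        out.append(SegmentAlignment(q0, q1, Segment(contig, r0, r0 + (q1 - q0),
                                                    "forward"),
                                    1 - mm / (q1 - q0)))
    rc = revcomp(contig_seq)
    for q0, q1, contig, r0, mm in _strand_alignments(rc, index, min_len):
        out.append(SegmentAlignment(n - q1, n - q0,
                                    Segment(contig, r0, r0 + (q1 - q0), "reverse"),
                                    1 - mm / (q1 - q0)))
    # drop alignments strictly contained in a longer one on the contig
    out.sort(key=lambda a: (a.contig_start, -(a.contig_end)))
    kept: list[SegmentAlignment] = []
    for a in out:
        if any(b.contig_start <= a.contig_start and a.contig_end <= b.contig_end
               and b.length > a.length for b in out):
            continue
        kept.append(a)
    return [a for a in kept if a.identity >= min_identity]


# ---------------------------------------------------------------------------
# chain selection
# ---------------------------------------------------------------------------

def chain_segments(alignments: list[SegmentAlignment], contig_length: int,
                   allowed_overlap: int = 20, min_chain_coverage: float = 0.95,
                   ) -> tuple[list[SegmentAlignment], list[int], float]:
    """Select the maximum-weight ordered tiling of the contig.

    Weighted interval scheduling over contig intervals (weight = aligned
    length x identity); consecutive alignments may overlap on the contig by
    up to ``allowed_overlap`` bases — that overlap is the junction's
    microhomology and is resolved by left-aligning the junction (the
    acceptor alignment is trimmed by the full overlap).  Returns the
    trimmed chain, the per-junction microhomology lengths, and the fraction
    of the contig covered.
    """
    if not alignments:
        raise ValueError("no alignments to chain")
    alns = sorted(alignments, key=lambda a: (a.contig_end, a.contig_start))
    n = len(alns)
    score = [a.weight for a in alns]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if alns[j].contig_end - alns[i].contig_start <= min(
                    allowed_overlap, alns[j].length - 1, alns[i].length - 1) \
                    and alns[j].contig_start < alns[i].contig_start:
                cand = score[j] + alns[i].weight
                if cand > score[i] + 1e-12:
                    score[i] = cand
                    prev[i] = j
    best_i = max(range(n), key=lambda i: (score[i], -alns[i].contig_start))
    chain: list[SegmentAlignment] = []
    i = best_i
    while i != -1:
        chain.append(alns[i])
        i = prev[i]
    chain.reverse()

    # left-align junctions: trim each acceptor by its overlap with the donor
    mh: list[int] = []
    trimmed: list[SegmentAlignment] = [chain[0]]
    for nxt in chain[1:]:
        donor = trimmed[-1]
        ov = max(0, donor.contig_end - nxt.contig_start)
        mh.append(ov)
        seg = nxt.segment
        if ov:
            if seg.orientation == "forward":
                seg = Segment(seg.contig, seg.start + ov, seg.end, "forward")
            else:
                seg = Segment(seg.contig, seg.start, seg.end - ov, "reverse")
        trimmed.append(SegmentAlignment(nxt.contig_start + ov, nxt.contig_end,
                                        seg, nxt.identity))

    covered = sum(a.length for a in trimmed) / contig_length
    return trimmed, mh, covered
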