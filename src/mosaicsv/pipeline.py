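"""End-to-end workflow: discovery, somatic filtering, assembly, resolution.

The resolver works junction-wise: every assembled contig that spans one or
more novel adjacencies contributes (donor breakpoint → acceptor breakpoint)
junctions; a depth-first walk then orders those junctions into the unique
segment chain that starts and ends collinearly on the anchor contig.  This
reconstructs alleles whose interior segments are far longer than a read —
the interior needs no read coverage at the SV locus because the segment
span is implied by consecutive junction breakpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .assembly import KmerIndex, assemble_contigs, align_contig, chain_segments
from .config import DEFAULT_CONFIG, PipelineConfig
from .discovery import (InsertStats, SvCall, call_somatic_pairwise,
                        cluster_breakpoints, estimate_insert_stats,
                        extract_abnormal_reads, flag_mda_artifacts,
                        group_adjacent_complex, merge_reciprocal, pair_and_type,
                        recurrence_filter)
from .genome import ReferenceGenome, Segment
from .rearrangement import RearrangementModel, model_from_chain
from .resolve import explanation_score
from .simulate import AlignmentRecord

log = logging.getLogger("mosaicsv.pipeline")


@dataclass(frozen=True)
class Junction:
    """A novel adjacency: synthesis leaves the donor template and resumes
    on the acceptor template."""

    donor_contig: str
    donor_pos: int
    donor_orient: str       # forward | reverse
    acceptor_contig: str
    acceptor_pos: int
    acceptor_orient: str
    mh: int = 0
    primary: bool = True    # left-homology-dominant (allele-forward) form

    def key(self) -> tuple:
        return (self.donor_contig, self.donor_pos, self.donor_orient,
                self.acceptor_contig, self.acceptor_pos, self.acceptor_orient)


def discover_sample(records: list[AlignmentRecord], ref: ReferenceGenome,
                    sample_id: str, config: PipelineConfig = DEFAULT_CONFIG,
                    insert_stats: InsertStats | None = None) -> list[SvCall]:
    """Split/discordant-read discovery for one sample (no somatic filtering)."""
    if insert_stats is None:
        insert_stats = estimate_insert_stats(records)
    abnormal = extract_abnormal_reads(records, config=config,
                                      insert_stats=insert_stats)
    candidates = cluster_breakpoints(abnormal, config)
    calls = pair_and_type(candidates, ref, sample_id, config)
    return merge_reciprocal(calls, config)


def somatic_workflow(samples: dict[str, list[AlignmentRecord]],
                     ref: ReferenceGenome,
                     config: PipelineConfig = DEFAULT_CONFIG,
                     ) -> tuple[list[SvCall], list[list[SvCall]]]:
    """Clone-to-clone somatic calling across all samples of one brain.

    Every clone is compared against every other clone; calls voted somatic
    consistently across comparisons are retained, merged reciprocally, and
    grouped into complex SVs, with MDA artifact groups flagged.
    Returns (mosaic calls, adjacency groups).
    """
    if len(samples) < 2:
        raise ValueError("somatic comparison needs at least two clones")
    stats = {s: estimate_insert_stats(r) for s, r in samples.items()}
    abnormal = {s: extract_abnormal_reads(r, config=config, insert_stats=stats[s])
                for s, r in samples.items()}
    calls_by_clone: dict[str, list[SvCall]] = {}
    for s, records in samples.items():
        candidates = cluster_breakpoints(abnormal[s], config)
        calls = pair_and_type(candidates, ref, s, config)
        calls = merge_reciprocal(calls, config)
        call_somatic_pairwise(calls, {k: v for k, v in abnormal.items() if k != s},
                              config)
        calls_by_clone[s] = calls
    mosaic = recurrence_filter(calls_by_clone, config)
    groups = group_adjacent_complex(mosaic, config)
    flag_mda_artifacts(groups, config)
    return mosaic, groups


# ---------------------------------------------------------------------------
# junction extraction and chain walking
# ---------------------------------------------------------------------------

def junctions_from_contig(contig_seq: str, ref: ReferenceGenome,
                          index: KmerIndex | None = None,
                          config: PipelineConfig = DEFAULT_CONFIG) -> list[Junction]:
    """Novel adjacencies spanned by one assembled contig."""
    alns = align_contig(contig_seq, ref, index=index, seed_k=config.seed_k,
                        min_identity=config.min_identity)
    if not alns:
        return []
    chain, mhs, _cov = chain_segments(alns, len(contig_seq),
                                      allowed_overlap=config.max_mh)
    out = []
    for prev, nxt, mh in zip(chain, chain[1:], mhs):
        d, a = prev.segment, nxt.segment
        out.append(Junction(
            d.contig, d.end if d.orientation == "forward" else d.start,
            d.orientation,
            a.contig, a.start if a.orientation == "forward" else a.end,
            a.orientation, mh))
    return out


def _flip(orient: str) -> str:
    return "reverse" if orient == "forward" else "forward"


def _same_directed(a: Junction, b: Junction, tol: int) -> bool:
    return (a.donor_contig == b.donor_contig and a.donor_orient == b.donor_orient
            and a.acceptor_contig == b.acceptor_contig
            and a.acceptor_orient == b.acceptor_orient
            and abs(a.donor_pos - b.donor_pos) <= tol
            and abs(a.acceptor_pos - b.acceptor_pos) <= tol)


def _mirrors(a: Junction, b: Junction, tol: int) -> bool:
    """True when ``b`` is the same physical adjacency traversed the other
    way (positions may shift by up to the microhomology length)."""
    t = tol + max(a.mh, b.mh)
    return (b.donor_contig == a.acceptor_contig
            and b.donor_orient == _flip(a.acceptor_orient)
            and abs(b.donor_pos - a.acceptor_pos) <= t
            and b.acceptor_contig == a.donor_contig
            and b.acceptor_orient == _flip(a.donor_orient)
            and abs(b.acceptor_pos - a.donor_pos) <= t)


def group_junctions(junctions: list[Junction], tol: int = 10,
                    ) -> list[list[Junction]]:
    """Group directed junction observations into physical-adjacency classes.

    The same adjacency can be observed in both traversal directions (the
    assembled contig's orientation is arbitrary); each class keeps every
    directed representation so the chain walk can traverse it either way
    while consuming the adjacency once.
    """
    classes: list[list[Junction]] = []
    for j in sorted(junctions, key=lambda j: j.key()):
        for cl in classes:
            if any(_same_directed(j, k, tol) or _mirrors(j, k, tol) for k in cl):
                if not any(_same_directed(j, k, tol) for k in cl):
                    cl.append(j)
                break
        else:
            classes.append([j])
    return classes


def walk_chain_all(junctions: list[Junction] | list[list[Junction]],
                   anchor_contig: str,
                   ) -> list[tuple[int, int, list[Segment], list[int]]]:
    """All complete junction walks anchored on ``anchor_contig``.

    Junctions may be given as directed observations or as
    mirror-equivalence classes (see :func:`group_junctions`).  Every
    junction whose donor is collinear on the anchor contig is tried as the
    left-flank junction; a depth-first search looks for walks consuming
    every adjacency exactly once and returning to the anchor contig in
    forward orientation.  Each solution is (anchor_start, anchor_end,
    chain, junction_mh); co-optimal solutions arise when the junction set
    alone cannot pick the traversal direction and are disambiguated by the
    caller (read support, then smallest anchor span).
    """
    if junctions and isinstance(junctions[0], Junction):
        classes = [[j] for j in junctions]
    else:
        classes = [list(cl) for cl in junctions]
    n = len(classes)
    if n == 0:
        return []

    def successors(state, used):
        contig, pos, orient = state
        for i, cl in enumerate(classes):
            if used[i]:
                continue
            for j in cl:
                if j.donor_contig != contig or j.donor_orient != orient:
                    continue
                if orient == "forward" and j.donor_pos >= pos:
                    yield i, j, (Segment(contig, pos, j.donor_pos, "forward")
                                 if j.donor_pos > pos else None)
                elif orient == "reverse" and j.donor_pos <= pos:
                    yield i, j, (Segment(contig, j.donor_pos, pos, "reverse")
                                 if j.donor_pos < pos else None)

    solutions: list[tuple[int, int, int, list[Segment], list[int], int]] = []

    def dfs(start_pos, state, used, chain, mhs, n_primary):
        if len(solutions) >= 100:
            return
        if all(used):
            contig, pos, orient = state
            if contig == anchor_contig and orient == "forward" \
                    and pos >= start_pos:
                solutions.append((pos - start_pos, start_pos, pos,
                                  list(chain), list(mhs), n_primary))
            return
        for i, j, seg in successors(state, used):
            used[i] = True
            nxt_state = (j.acceptor_contig, j.acceptor_pos, j.acceptor_orient)
            new_chain = chain + ([seg] if seg is not None else [])
            dfs(start_pos, nxt_state, used, new_chain, mhs + [j.mh],
                n_primary + (1 if j.primary else 0))
            used[i] = False

    for i, cl in enumerate(classes):
        for j in cl:
            if j.donor_contig != anchor_contig or j.donor_orient != "forward":
                continue
            used = [False] * n
            used[i] = True
            dfs(j.donor_pos,
                (j.acceptor_contig, j.acceptor_pos, j.acceptor_orient),
                used, [], [j.mh], 1 if j.primary else 0)
    # prefer walks traversing the allele forward (most left-aligned primary
    # forms), then the smallest anchor region and shortest chain
    uniq = []
    seen = set()
    for _span, a0, a1, chain, mhs, n_prim in sorted(
            solutions,
            key=lambda s: (-s[5], s[0], sum(len(x) for x in s[3]), s[1])):
        key = (a0, a1, tuple(chain))
        if key not in seen:
            seen.add(key)
            uniq.append((a0, a1, chain, mhs, n_prim))
    return uniq


def walk_chain(junctions: list[Junction] | list[list[Junction]],
               anchor_contig: str,
               ) -> tuple[int, int, list[Segment], list[int]] | None:
    """Best single walk; see :func:`walk_chain_all`."""
    solutions = walk_chain_all(junctions, anchor_contig)
    return solutions[0][:4] if solutions else None


def junction_homology_lr(ref: ReferenceGenome, j: Junction,
                         max_mh: int = 20) -> tuple[int, int]:
    """(left, right) homology of a directed junction on the reference.

    Left homology: the donor's last bases equal the acceptor template's
    preceding bases (the junction is left-aligned when this dominates);
    right homology: the donor's continuation equals the acceptor's first
    bases (the junction could shift forward).
    """
    from .rearrangement import _common_prefix, _common_suffix, template_flanks

    if j.donor_orient == "forward":
        dl, dr = template_flanks(ref, Segment(j.donor_contig, max(0, j.donor_pos - 1),
                                              j.donor_pos, "forward"),
                                 at_start=False, width=max_mh + 1)
    else:
        dl, dr = template_flanks(ref, Segment(j.donor_contig, j.donor_pos,
                                              j.donor_pos + 1, "reverse"),
                                 at_start=False, width=max_mh + 1)
    if j.acceptor_orient == "forward":
        al, ar = template_flanks(ref, Segment(j.acceptor_contig, j.acceptor_pos,
                                              j.acceptor_pos + 1, "forward"),
                                 at_start=True, width=max_mh + 1)
    else:
        al, ar = template_flanks(ref, Segment(j.acceptor_contig,
                                              max(0, j.acceptor_pos - 1),
                                              j.acceptor_pos, "reverse"),
                                 at_start=True, width=max_mh + 1)
    return (_common_suffix(dl, al, max_mh), _common_prefix(dr, ar, max_mh))


def junction_homology(ref: ReferenceGenome, j: Junction, max_mh: int = 20) -> int:
    """MH operator applied to a directed junction on the reference."""
    left, right = junction_homology_lr(ref, j, max_mh)
    return max(left, right)


def mirror_junction(j: Junction) -> Junction:
    """The same adjacency traversed the other way, left-aligned in that
    direction (positions shift by the microhomology length)."""
    m = j.mh
    dp = j.acceptor_pos - m if j.acceptor_orient == "forward" else j.acceptor_pos + m
    ap = j.donor_pos - m if j.donor_orient == "forward" else j.donor_pos + m
    return Junction(j.acceptor_contig, dp, _flip(j.acceptor_orient),
                    j.donor_contig, ap, _flip(j.donor_orient), m,
                    primary=not j.primary)


def snap_junctions(junctions: list[Junction],
                   clipped: list[tuple[str, int, str, str]],
                   ref: ReferenceGenome,
                   config: PipelineConfig) -> list[Junction]:
    """Anchor junction boundaries on soft-clip positions and remeasure MH.

    Contig consensus can be off by a base or two at low-depth columns, and
    chimeric assembly seams inside duplicated sequence mimic junctions;
    soft-clip positions are exact and plentiful, so every boundary is
    snapped to the nearest clip position (majority within tolerance) and
    junctions with no clip support on either side are discarded.  The
    microhomology is then re-measured on the reference.
    """
    by_contig: dict[str, dict[int, int]] = {}
    for rc, rp, _rid, _seq in clipped:
        by_contig.setdefault(rc, {})[rp] = by_contig.get(rc, {}).get(rp, 0) + 1

    def snap(contig: str, pos: int, tol: int) -> int | None:
        best = None
        for p, n in by_contig.get(contig, {}).items():
            d = abs(p - pos)
            if d <= tol and (best is None or (d, -n) < (best[0], -best[1])):
                best = (d, n, p)
        return None if best is None else best[2]

    out = []
    for j in junctions:
        tol = config.cluster_tolerance + j.mh
        dp = snap(j.donor_contig, j.donor_pos, tol)
        ap = snap(j.acceptor_contig, j.acceptor_pos, tol)
        if dp is None and ap is None:
            continue
        snapped = Junction(j.donor_contig, dp if dp is not None else j.donor_pos,
                           j.donor_orient,
                           j.acceptor_contig, ap if ap is not None else j.acceptor_pos,
                           j.acceptor_orient, j.mh)
        # clip positions mark the left-aligned (allele-forward) placement;
        # a mirror-extracted junction snapped onto them must be flipped back
        # into the direction where left homology dominates
        left, right = junction_homology_lr(ref, snapped, config.max_mh)
        if right > left:
            snapped = Junction(snapped.acceptor_contig, snapped.acceptor_pos,
                               _flip(snapped.acceptor_orient),
                               snapped.donor_contig, snapped.donor_pos,
                               _flip(snapped.donor_orient), right)
        else:
            snapped = Junction(snapped.donor_contig, snapped.donor_pos,
                               snapped.donor_orient, snapped.acceptor_contig,
                               snapped.acceptor_pos, snapped.acceptor_orient, left)
        out.append(snapped)
    return out


def canonical_classes(junctions: list[Junction], ref: ReferenceGenome,
                      tol: int = 10) -> list[list[Junction]]:
    """Snap-corrected junctions grouped into classes of both traversal
    directions: each class holds a representation and its synthesized
    mirror, so the walk never depends on which orientation was assembled."""
    classes: list[list[Junction]] = []
    for j in junctions:
        m = mirror_junction(j)
        placed = False
        for cl in classes:
            if any(_same_directed(j, k, tol) or _same_directed(m, k, tol)
                   for k in cl):
                placed = True
                break
        if not placed:
            classes.append([j, m])
    return classes


def _fragment_consistent(target: str, s1: str, s2: str, max_ed: int) -> bool:
    """Do two template-forward mate sequences fit the allele as one fragment?

    Both mates must align to the candidate allele on the same strand and in
    order — the signature that breaks when a walk flips a sub-chain's
    orientation (single reads align either strand and cannot tell).
    """
    import edlib

    from .genome import revcomp

    for a, b in ((s1, s2), (revcomp(s2), revcomp(s1))):
        ra = edlib.align(a, target, mode="HW", task="locations")
        rb = edlib.align(b, target, mode="HW", task="locations")
        if 0 <= ra["editDistance"] <= max_ed and 0 <= rb["editDistance"] <= max_ed:
            # repeated content can yield several co-best placements; the
            # fragment fits if any ordered combination exists
            if any(la[0] <= lb[1] + 1
                   for la in ra["locations"] for lb in rb["locations"]):
                return True
    return False


def _fragment_score(model_target: str, pairs: list[tuple[str, str]],
                    max_ed: int) -> float:
    if not pairs:
        return 0.0
    ok = sum(1 for s1, s2 in pairs
             if _fragment_consistent(model_target, s1, s2, max_ed))
    return ok / len(pairs)


def resolve_group(group: list[SvCall], records: list[AlignmentRecord],
                  ref: ReferenceGenome, index: KmerIndex | None = None,
                  config: PipelineConfig = DEFAULT_CONFIG,
                  insert_stats: InsertStats | None = None,
                  ) -> tuple[RearrangementModel | None, float]:
    """Assemble and resolve one adjacency group of calls.

    Junctions are chased iteratively: every resolved junction exposes new
    donor/acceptor loci (possibly on other chromosomes), whose clipped
    reads are assembled in turn until the junction set closes.  Returns
    (model, explanation score); (None, 0.0) when unresolved.  The model's
    ``contig_sequence`` holds the reconstructed ALT allele with
    window-length reference flanks, against which the score is computed.
    """
    if insert_stats is None:
        insert_stats = estimate_insert_stats(records)
    abnormal_all = extract_abnormal_reads(records, config=config,
                                          insert_stats=insert_stats)
    # clipped reads indexed by their clip coordinate for fast locus pulls
    clipped: list[tuple[str, int, str, str]] = []  # (contig, clip_pos, id, seq)
    for r in abnormal_all:
        if r.clip_right > config.soft_clip_min:
            clipped.append((r.contig, r.end, r.read_id, r.sequence))
        if r.clip_left > config.soft_clip_min:
            clipped.append((r.contig, r.pos, r.read_id, r.sequence))
    # shorter clips are unusable for assembly but their positions are exact
    # breakpoint markers for boundary snapping
    clip_marks: list[tuple[str, int, str, str]] = list(clipped)
    for r in records:
        if config.soft_clip_min >= r.clip_right >= 1:
            clip_marks.append((r.contig, r.end, r.read_id, ""))
        if config.soft_clip_min >= r.clip_left >= 1:
            clip_marks.append((r.contig, r.pos, r.read_id, ""))

    contigs = {}
    for c in group:
        for bc, bp, _side in c.breakpoints:
            contigs.setdefault(bc, []).append(bp)
    anchor_contig = max(contigs, key=lambda c: len(contigs[c]))

    w = config.window
    visited: set[tuple[str, int]] = set()
    pending: set[tuple[str, int]] = {(bc, bp) for c in group
                                     for bc, bp, _s in c.breakpoints}
    pool: dict[str, str] = {}          # read id -> sequence, across all loci
    junctions: list[Junction] = []
    from .genome import revcomp
    for _round in range(10):
        new_loci: set[tuple[str, int]] = set()
        grew = False
        for contig_name, pos in sorted(pending):
            key = (contig_name, pos // (w // 2))
            if key in visited:
                continue
            visited.add(key)
            for rc, rp, rid, seq in clipped:
                if rc == contig_name and abs(rp - pos) <= w and rid not in pool:
                    pool[rid] = seq
                    grew = True
        if grew and len(pool) >= 2:
            # one assembly over every locus pulled so far: reads from both
            # sides of a short segment must meet in one deep contig
            junctions = []
            for contig in assemble_contigs(sorted(pool.items()),
                                           config.min_overlap,
                                           config.max_mismatch):
                if len(contig.sequence) < 2 * config.seed_k:
                    continue
                # both orientations: the contig's strand is arbitrary and the
                # walk needs the representation matching its traversal
                for seq in (contig.sequence, revcomp(contig.sequence)):
                    junctions.extend(junctions_from_contig(
                        seq, ref, index=index, config=config))
            junctions = snap_junctions(junctions, clip_marks, ref, config)
        classes = canonical_classes(junctions, ref, tol=config.cluster_tolerance)
        junctions = [cl[0] for cl in classes]
        for cl in classes:
            for j in cl:
                new_loci.add((j.donor_contig, j.donor_pos))
                new_loci.add((j.acceptor_contig, j.acceptor_pos))
        pending = {(c, p) for c, p in new_loci
                   if (c, p // (w // 2)) not in visited}
        if not pending:
            break
    classes = canonical_classes(junctions, ref, tol=config.cluster_tolerance)
    # candidate anchors: the group's majority contig first, then any other
    # contig carrying a forward donor (inter-chromosomal anchors)
    candidates = [anchor_contig]
    for cl in classes:
        for j in cl:
            if j.donor_orient == "forward" and j.donor_contig not in candidates:
                candidates.append(j.donor_contig)
    solutions: list[tuple[str, int, int, list[Segment], list[int], int]] = []
    for cand in candidates:
        for a0, a1, chain, mhs, n_prim in walk_chain_all(classes, cand):
            solutions.append((cand, a0, a1, chain, mhs, n_prim))
        if solutions:
            break
    if not solutions:
        log.info("group on %s unresolved (%d junction classes)",
                 anchor_contig, len(classes))
        return None, 0.0

    # abnormal reads around any junction locus: the shared evidence set that
    # disambiguates co-optimal walks (fragments must fit the allele with
    # consistent mate orientation, which single reads cannot test)
    loci = {(j.donor_contig, j.donor_pos) for cl in classes for j in cl} \
        | {(j.acceptor_contig, j.acceptor_pos) for cl in classes for j in cl}
    score_reads = [r for r in abnormal_all
                   if any(r.contig == lc and r.pos - w <= lp <= r.end + w
                          for lc, lp in loci)]
    from .genome import revcomp as _rc
    # fragments carrying a soft-clip at a junction boundary: the informative
    # pairs (anything else aligns equally well to every interpretation)
    jt = config.cluster_tolerance + config.max_mh
    near_ids = {rid.rsplit("/", 1)[0] for rc_, rp, rid, _seq in clipped
                if any(rc_ == lc and abs(rp - lp) <= jt for lc, lp in loci)}
    mates: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        base = r.read_id.rsplit("/", 1)[0]
        if base in near_ids:
            mates.setdefault(base, []).append(r)
    pairs = []
    for members in mates.values():
        if len(members) == 2:
            a, b = sorted(members, key=lambda r: r.read_id)
            pairs.append((a.sequence if a.strand == "+" else _rc(a.sequence),
                          b.sequence if b.strand == "+" else _rc(b.sequence)))

    # selection among co-optimal walks: (1) fragment support — walks that
    # flip a sub-chain against the data lose pairs; (2) allele-forward
    # traversal (most left-aligned primary junction forms); (3) parsimony —
    # among data-equivalent interpretations (a distal inverted insertion is
    # indistinguishable from a genome-scale inversion plus duplication),
    # the smallest total rearranged footprint, then jump distance
    best: tuple[tuple, RearrangementModel] | None = None
    for cand, a0, a1, chain, mhs, n_prim in solutions[:10]:
        model = model_from_chain(cand, a0, a1, chain, junction_mh=mhs)
        ref_seq = ref.contigs[cand]
        alt = "".join(ref.fetch(s) for s in chain)
        model.contig_sequence = (ref_seq[max(0, a0 - w):a0] + alt
                                 + ref_seq[a1:a1 + w])
        n_ok = sum(1 for s1, s2 in pairs
                   if _fragment_consistent(model.contig_sequence, s1, s2,
                                           config.max_mismatch))
        footprint = (a1 - a0) + sum(len(s) for s in chain)
        jump_sum = sum(d for d in model.switch_distances if d is not None)
        key = (n_ok, n_prim, -footprint, -(a1 - a0), -jump_sum)
        if best is None or key > best[0]:
            best = (key, model)
    model = best[1]
    score = explanation_score(model, score_reads, config) if score_reads else 0.0
    return model, score
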