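"""Ready-made simulation scenarios.

These builders define the study conditions the package is validated
against: clones sequenced at 30x with clonal SVs at ~50% allele fraction,
subclonal SVs at lower fractions, complex alleles with 2-4 bp junction
microhomologies, inter-chromosomal insertions, clone-private SNVs, and
MDA chimera artifacts.
"""

from __future__ import annotations

import numpy as np

from .alleles import AltAlleleSpec, TruthRecord, implant_sv
from .genome import ReferenceGenome, Segment, build_reference
from .rearrangement import LOCAL_SPAN
from .simulate import CloneSpec


def random_complex_spec(rng: np.random.Generator, ref: ReferenceGenome,
                        label: str, n_segments: tuple[int, int] = (1, 5),
                        seg_size: tuple[int, int] = (50, 2000),
                        mh_range: tuple[int, int] = (2, 4),
                        deleted_range: tuple[int, int] = (0, 2000),
                        local_margin: int = 3000,
                        min_boundary_gap: int = 60) -> AltAlleleSpec:
    """Draw a random complex allele: a deleted span at a random anchor
    replaced by 1-5 oriented segments (local or distal/inter-chromosomal)
    with the requested junction microhomologies.

    Segment boundaries are kept at least ``min_boundary_gap`` apart so
    every junction is distinct; immediate identical repeats are avoided.
    """
    names = list(ref.contigs)
    for _attempt in range(200):
        anchor_contig = names[int(rng.integers(0, len(names)))]
        L = ref.length(anchor_contig)
        anchor = int(rng.integers(local_margin + 2000, L - local_margin - 4000))
        deleted_span = int(rng.integers(deleted_range[0], deleted_range[1] + 1))
        nseg = int(rng.integers(n_segments[0], n_segments[1] + 1))
        boundaries = {anchor_contig: [anchor, anchor + deleted_span]}
        chain: list[Segment] = []
        ok = True
        for _ in range(nseg):
            size = int(rng.integers(seg_size[0], seg_size[1] + 1))
            orientation = "forward" if rng.random() < 0.5 else "reverse"
            if rng.random() < 0.4:
                # local segment: duplicates / inverts sequence near the anchor
                # but clear of the replaced span itself (a segment overlapping
                # the anchor boundary makes the anchor placement ambiguous)
                contig = anchor_contig
                if rng.random() < 0.5:
                    start = anchor - 100 - size - int(rng.integers(0, local_margin))
                else:
                    start = anchor + deleted_span + 100 + int(rng.integers(0, local_margin))
            else:
                contig = names[int(rng.integers(0, len(names)))]
                cl = ref.length(contig)
                start = int(rng.integers(1000, cl - 1000 - size))
                if contig == anchor_contig and abs(start - anchor) < LOCAL_SPAN + 2000:
                    ok = False
                    break
            if start < 100 or start + size > ref.length(contig) - 100:
                ok = False
                break
            seg = Segment(contig, start, start + size, orientation)
            if chain and chain[-1] == seg:
                ok = False
                break
            bl = boundaries.setdefault(contig, [])
            if any(abs(b - x) < min_boundary_gap
                   for b in bl for x in (seg.start, seg.end)):
                ok = False
                break
            bl.extend([seg.start, seg.end])
            chain.append(seg)
        if not ok:
            continue
        mh = [int(rng.integers(mh_range[0], mh_range[1] + 1))
              for _ in range(len(chain) + 1)]
        if not chain:
            if deleted_span < max(mh[0], 100):
                continue
        elif deleted_span == 0 and not chain:
            continue
        return AltAlleleSpec(anchor=(anchor_contig, anchor),
                             deleted_span=deleted_span, chain=chain,
                             junction_mh=mh, label=label)
    raise RuntimeError("could not draw a valid allele spec")


def implant_random_alleles(ref: ReferenceGenome, n: int, seed: int,
                           **spec_kwargs) -> dict[str, TruthRecord]:
    """Implant ``n`` random complex alleles, retrying drawings whose
    microhomology edits would conflict."""
    rng = np.random.default_rng(seed)
    truth: dict[str, TruthRecord] = {}
    i = 0
    attempts = 0
    while len(truth) < n and attempts < 50 * n + 50:
        attempts += 1
        label = f"sv{i}"
        spec = random_complex_spec(rng, ref, label, **spec_kwargs)
        # keep alleles apart from already-implanted ones
        clash = False
        for tr in truth.values():
            if tr.anchor_contig == spec.anchor_contig and \
                    abs(tr.anchor_start - spec.anchor_start) < 12_000:
                clash = True
                break
        if clash:
            continue
        trial = ref.copy()
        try:
            implant_sv(trial, spec)
        except ValueError:
            continue
        _alt, tr = implant_sv(ref, spec)
        truth[label] = tr
        i += 1
    if len(truth) < n:
        raise RuntimeError("could not implant the requested number of alleles")
    return truth


def simple_deletion_scenario(seed: int, deletion_size: int = 800,
                             n_clones: int = 2, coverage: float = 30.0,
                             contig_length: int = 30_000,
                             ) -> tuple[ReferenceGenome, dict[str, TruthRecord],
                                        list[CloneSpec]]:
    """One clonal heterozygous deletion private to clone 1, plus controls."""
    ref = build_reference(seed, n_contigs=2, contig_length=contig_length,
                          snp_density=0.0005)
    anchor = contig_length // 2
    spec = AltAlleleSpec(anchor=("chr1", anchor), deleted_span=deletion_size,
                         chain=[], junction_mh=[2], label="del1")
    _alt, truth = implant_sv(ref, spec)
    clones = [CloneSpec(clone_id="clone1", harbored_svs=[("del1", 1.0)],
                        coverage=coverage)]
    for i in range(2, n_clones + 1):
        clones.append(CloneSpec(clone_id=f"clone{i}", coverage=coverage))
    return ref, {"del1": truth}, clones


def germline_panel_scenario(seed: int, n_svs: int = 100,
                            contig_length: int = 150_000,
                            coverage: float = 30.0,
                            ) -> tuple[ReferenceGenome, dict[str, TruthRecord],
                                       list[CloneSpec]]:
    """``n_svs`` germline deletions shared by two bulks and one clone.

    Used for the discovery-sensitivity estimate: the truth set is derived
    from the two bulk call sets, and the clone's calls are scored against
    it.
    """
    rng = np.random.default_rng(seed)
    ref = build_reference(seed + 1, n_contigs=2, contig_length=contig_length,
                          snp_density=0.0002)
    truth: dict[str, TruthRecord] = {}
    per = (n_svs + 1) // 2
    spacing = (contig_length - 8000) // per
    if spacing < 2600:
        raise ValueError("genome too small for the requested SV count")
    for i in range(n_svs):
        contig = "chr1" if i < per else "chr2"
        j = i if i < per else i - per
        local = 4000 + j * spacing
        size = int(rng.integers(500, 1500))
        spec = AltAlleleSpec(anchor=(contig, local), deleted_span=size,
                             chain=[], junction_mh=[int(rng.integers(0, 5))],
                             label=f"g{i}")
        _alt, tr = implant_sv(ref, spec)
        truth[f"g{i}"] = tr
    carried = [(lab, 1.0) for lab in truth]
    samples = [
        CloneSpec(clone_id="bulk1", harbored_svs=carried, coverage=coverage),
        CloneSpec(clone_id="bulk2", harbored_svs=carried, coverage=coverage),
        CloneSpec(clone_id="clone1", harbored_svs=carried, coverage=coverage),
    ]
    return ref, truth, samples
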