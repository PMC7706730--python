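"""Synthetic reference genomes: contigs, assembly gaps, and germline SNP panels.

The forge produces deterministic random genomes with a controlled GC
fraction, optional assembly-gap intervals, and disjoint heterozygous /
homozygous germline SNP site panels placed outside the gaps.  These genomes
are the substrate into which structural-variant alleles are implanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Segment:
    """An oriented reference interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment coordinates {self.start}:{self.end}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_reverse(self) -> bool:
        return self.orientation == "reverse"


@dataclass
class ReferenceGenome:
    """Contigs plus gap annotation and germline SNP panels.

    het_snp_sites / hom_snp_sites are lists of (contig, pos, ref_base,
    alt_base); the two sets are disjoint by construction.  Gap intervals are
    half-open (contig, start, end) spans of 'N'-like inaccessible sequence.
    """

    contigs: dict[str, str]
    gap_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    het_snp_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    hom_snp_sites: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name} is empty")
        for contig, start, end in self.gap_intervals:
            if not 0 <= start <= end <= len(self.contigs[contig]):
                raise ValueError(f"gap {contig}:{start}-{end} out of bounds")
        for contig, pos, ref, _alt in self.het_snp_sites + self.hom_snp_sites:
            if not 0 <= pos < len(self.contigs[contig]):
                raise ValueError(f"SNP position {contig}:{pos} out of bounds")
        het = {(c, p) for c, p, *_ in self.het_snp_sites}
        hom = {(c, p) for c, p, *_ in self.hom_snp_sites}
        if het & hom:
            raise ValueError("het and hom SNP site sets overlap")

    def fetch(self, segment: Segment) -> str:
        """Sequence of an oriented segment (reverse segments reverse-complemented)."""
        seq = self.contigs[segment.contig][segment.start:segment.end]
        return revcomp(seq) if segment.is_reverse else seq

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def copy(self) -> "ReferenceGenome":
        return ReferenceGenome(
            contigs=dict(self.contigs),
            gap_intervals=list(self.gap_intervals),
            het_snp_sites=list(self.het_snp_sites),
            hom_snp_sites=list(self.hom_snp_sites),
        )

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.contigs:
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA reader returning name -> sequence (uppercased)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def build_reference(
    seed: int,
    n_contigs: int = 2,
    contig_length: int = 100_000,
    gc_fraction: float = 0.4,
    snp_density: float = 0.001,
    gap_spec: Iterable[tuple[int, int, int]] | None = None,
) -> ReferenceGenome:
    """Forge a deterministic random reference genome.

    Parameters
    ----------
    seed : int
        Seed for the generator; identical seeds give byte-identical genomes.
    n_contigs, contig_length : int
        Genome shape.  Lengths of at least ~10 kb are recommended so that
        2-kb windows and flanks fit.
    gc_fraction : float
        Expected G+C fraction of the random sequence.
    snp_density : float
        Per-base probability of a germline SNP site; sites are split evenly
        between heterozygous and homozygous panels and never fall in gaps.
        Densities above 0.1 are rejected as unrealistic.
    gap_spec : iterable of (contig_index, start, end), optional
        Assembly gaps to annotate (sequence is left random; the intervals
        are excluded from SNP placement and honored by the gap-exclusion
        filter downstream).
    """
    if contig_length <= 0 or n_contigs <= 0:
        raise ValueError("n_contigs and contig_length must be positive")
    if not 0 <= snp_density <= 0.1:
        raise ValueError("snp_density must be in [0, 0.1]")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
                  (1 - gc_fraction) / 2])
    contigs: dict[str, str] = {}
    for i in range(n_contigs):
        draws = rng.choice(4, size=contig_length, p=p)
        contigs[f"chr{i + 1}"] = "".join(_BASES[draws])

    names = list(contigs)
    gaps: list[tuple[str, int, int]] = []
    if gap_spec:
        for ci, start, end in gap_spec:
            contig = names[ci]
            if not 0 <= start < end <= contig_length:
                raise ValueError(f"gap {start}:{end} out of bounds")
            gaps.append((contig, start, end))

    het: list[tuple[str, int, str, str]] = []
    hom: list[tuple[str, int, str, str]] = []
    if snp_density > 0:
        for contig in names:
            seq = contigs[contig]
            n_sites = rng.binomial(contig_length, snp_density)
            positions = np.sort(rng.choice(contig_length, size=n_sites, replace=False))
            in_gap = np.zeros(contig_length, dtype=bool)
            for gc, gs, ge in gaps:
                if gc == contig:
                    in_gap[gs:ge] = True
            for j, pos in enumerate(int(x) for x in positions):
                if in_gap[pos]:
                    continue
                ref_base = seq[pos]
                alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                site = (contig, pos, ref_base, alt_base)
                (het if j % 2 == 0 else hom).append(site)

    return ReferenceGenome(contigs=contigs, gap_intervals=gaps,
                           het_snp_sites=het, hom_snp_sites=hom)
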