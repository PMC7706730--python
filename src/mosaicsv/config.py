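"""Pipeline-wide thresholds.

Every printed cutoff used by the discovery, resolution, genotyping and
filtering stages lives here so that a single object documents the operating
point of the whole workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    """Operating thresholds for the mosaic-SV workflow.

    Units are base pairs unless noted.  Defaults are the workflow's standard
    operating point for ~30x short-read clone sequencing.
    """

    # abnormal-read extraction
    soft_clip_min: int = 30          # a read is abnormal if clipped by MORE than this
    window: int = 2000               # locus neighborhood on either end of an event
    discordance_sds: float = 3.0     # insert-size cutoff: mean + k*SD

    # breakpoint clustering / typing
    min_split_support: int = 3
    cluster_tolerance: int = 10
    clip_match_identity: float = 0.9  # clipped-sequence agreement for pairing

    # merging / grouping
    reciprocal_overlap: float = 0.5
    adjacency: int = 1000            # complex-SV grouping distance
    recurrence_fraction: float = 0.8  # fraction of informative comparisons
    rescue_span: int = 10_000        # one-sided candidate partner search range

    # assembly / resolution
    min_overlap: int = 20
    max_mismatch: int = 2
    seed_k: int = 15
    min_identity: float = 0.9
    band: int = 30
    max_mh: int = 20
    min_chain_coverage: float = 0.95
    score_threshold: float = 0.8     # explanation score must EXCEED this

    # genotyping
    flank: int = 2000
    unique_margin: int = 5           # best-vs-second alignment score margin
    hom_fraction: float = 0.9        # ALT fraction calling a site homozygous
    hom_sample_fraction: float = 0.9
    clonality_alpha: float = 0.01

    # read-depth CNV post-filter
    bin_size: int = 200
    gap_exclusion: int = 1_000_000
    del_tissue_min: float = 1.6
    del_clone_max: float = 1.4
    cn_difference: float = 0.5
    clone_majority: float = 0.6
    dup_clone_min: float = 2.6
    dup_other_max: float = 2.4
    dup_tissue_as_printed: bool = False  # literal (inconsistent) tissue >= 2.4 clause

    # timing / ddPCR
    snv_rate: float = 5.1            # somatic SNVs per day per progenitor
    pg_per_genome: float = 10.0      # pg of DNA per diploid genome equivalent

    def __post_init__(self) -> None:
        for name in ("reciprocal_overlap", "recurrence_fraction", "clone_majority",
                     "min_identity", "min_chain_coverage", "score_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("soft_clip_min", "window", "cluster_tolerance", "adjacency",
                     "flank", "bin_size", "gap_exclusion", "min_split_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.snv_rate <= 0 or self.pg_per_genome <= 0:
            raise ValueError("rates must be positive")


DEFAULT_CONFIG = PipelineConfig()
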