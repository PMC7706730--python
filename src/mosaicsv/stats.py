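"""Lineage timing, discovery sensitivity, ddPCR math and incidence tests.

Timing rests on a molecular clock: somatic SNVs accumulate at a fixed rate
per day in each neural progenitor, so the SNVs private to each of two
clones sharing an SV date the divergence of their common ancestor, and the
brain's age places the SV's origin in developmental time (weeks
postconception).  ddPCR concentrations follow droplet Poisson statistics:
the copies-per-droplet rate is lambda = -ln(1 - k/n) for k positive
droplets of n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom


@dataclass
class TimingEstimate:
    """Divergence time of two clones from their private SNV counts."""

    divergence_days: float
    divergence_weeks_raw: float
    divergence_weeks: int          # half-up rounding for reporting
    n1: int
    n2: int
    rate: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def divergence_time(n1: int, n2: int, rate: float = 5.1) -> TimingEstimate:
    """Days since two clones diverged, from clone-private SNV counts.

    ``rate`` is the somatic SNV accumulation rate per day per progenitor
    (default 5.1).  divergence_days = mean(n1, n2) / rate; e.g. 53 and 65
    private SNVs give 11.57 days, reported as ~2 weeks.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n1 < 0 or n2 < 0:
        raise ValueError("SNV counts must be non-negative")
    days = ((n1 + n2) / 2) / rate
    weeks_raw = days / 7
    return TimingEstimate(days, weeks_raw, _round_half_up(weeks_raw), n1, n2, rate)


def origin_time(harvest_weeks_pc: float, timing: TimingEstimate) -> float:
    """Developmental origin (weeks postconception) of a shared event.

    origin = harvest age − divergence; e.g. harvest at 16 wk pc with a
    ~2-wk divergence places the event at ~14 wk pc.  A non-positive origin
    is implausible (the event would predate conception) and is rejected,
    with a warning at the exact boundary.
    """
    origin = harvest_weeks_pc - timing.divergence_weeks_raw
    if origin < 0:
        raise ValueError("divergence predates conception: check inputs")
    if origin == 0:
        warnings.warn("origin exactly at conception is implausible", stacklevel=2)
    return origin


# ---------------------------------------------------------------------------
# discovery sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    truth_set_size: int
    per_clone: dict[str, float]
    mean_sensitivity: float | None


def _spans(calls) -> list[tuple[str, int, int]]:
    out = []
    for c in calls:
        if isinstance(c, tuple):
            out.append(c)
        else:
            out.append((c.contig, c.start, c.end))
    return out


def _reciprocal_match(a: tuple[str, int, int], b: tuple[str, int, int],
                      frac: float) -> bool:
    if a[0] != b[0]:
        return False
    ov = min(a[2], b[2]) - max(a[1], b[1])
    la, lb = a[2] - a[1], b[2] - b[1]
    return la > 0 and lb > 0 and ov >= frac * max(la, lb)


def estimate_sensitivity(clone_calls: dict[str, list], bulk1_calls, bulk2_calls,
                         reciprocal: float = 0.5) -> SensitivityReport:
    """Discovery sensitivity against a bulk-derived truth set.

    The truth set is the reciprocal-overlap intersection of two independent
    bulk call sets; each clone's sensitivity is the fraction of truth
    entries recovered (again at reciprocal overlap) among its calls.  An
    empty truth set yields an undefined (None) mean.
    """
    b1, b2 = _spans(bulk1_calls), _spans(bulk2_calls)
    truth = [a for a in b1 if any(_reciprocal_match(a, b, reciprocal) for b in b2)]
    per_clone: dict[str, float] = {}
    for clone_id, calls in clone_calls.items():
        spans = _spans(calls)
        if not truth:
            continue
        hit = sum(1 for t in truth
                  if any(_reciprocal_match(t, s, reciprocal) for s in spans))
        per_clone[clone_id] = hit / len(truth)
    mean = (sum(per_clone.values()) / len(per_clone)) if truth and per_clone else None
    return SensitivityReport(len(truth), per_clone, mean)


# ---------------------------------------------------------------------------
# ddPCR
# ---------------------------------------------------------------------------

@dataclass
class DdpcrResult:
    var_positive: int
    var_total: int
    ref_positive: int
    ref_total: int
    lambda_var: float
    lambda_ref: float
    allele_fraction: float
    ci_low: float
    ci_high: float


def _wilson(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def ddpcr_af(var_pos: int, var_total: int, ref_pos: int, ref_total: int) -> DdpcrResult:
    """Allele fraction from droplet counts, with a 95% CI.

    Each channel's copies-per-droplet rate is lambda = -ln(1 - k/n); the
    allele fraction is lambda_var / lambda_ref.  The CI propagates the
    Wilson interval of each positive-droplet fraction through the log
    transform and combines the two channels as independent errors.  A
    saturated channel (k = n) leaves lambda undefined and is rejected.
    """
    for k, n, name in ((var_pos, var_total, "variant"), (ref_pos, ref_total, "reference")):
        if n <= 0:
            raise ValueError(f"{name} channel has no droplets")
        if not 0 <= k <= n:
            raise ValueError(f"{name} channel positives exceed total")
        if k == n:
            raise ValueError(f"{name} channel saturated (all droplets positive)")
    if ref_pos == 0:
        raise ValueError("reference channel has no positive droplets")

    lam_v = -math.log(1 - var_pos / var_total)
    lam_r = -math.log(1 - ref_pos / ref_total)
    af = lam_v / lam_r

    lo_v, hi_v = _wilson(var_pos, var_total)
    lo_r, hi_r = _wilson(ref_pos, ref_total)
    lam = lambda p: -math.log(1 - p)
    z = 1.959963984540054
    sd_v = (lam(hi_v) - lam(lo_v)) / (2 * z)
    sd_r = (lam(hi_r) - lam(lo_r)) / (2 * z)
    if lam_v > 0:
        rel = math.sqrt((sd_v / lam_v) ** 2 + (sd_r / lam_r) ** 2)
        lo, hi = af * (1 - z * rel), af * (1 + z * rel)
    else:
        lo, hi = 0.0, lam(hi_v) / lam_r
    return DdpcrResult(var_pos, var_total, ref_pos, ref_total, lam_v, lam_r,
                       af, max(0.0, lo), hi)


def ddpcr_max_sensitivity(input_ng: float, pg_per_genome: float = 10.0,
                          ) -> tuple[float, float]:
    """(genome equivalents, minimum detectable fraction in percent).

    40 ng of input at 10 pg per diploid genome gives 4000 genome
    equivalents, hence a 1-in-4000 = 0.025% detection floor.  (The textbook
    diploid genome mass is ~6.6 pg; 10 pg is the round value consistent
    with the 40 ng → 4000 genomes arithmetic.)
    """
    if input_ng <= 0 or pg_per_genome <= 0:
        raise ValueError("inputs must be positive")
    genomes = input_ng * 1000 / pg_per_genome
    return genomes, 100.0 / genomes


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for a 2x2 table [[a, b], [c, d]].

    Standard minimum-likelihood convention: the p-value sums the
    hypergeometric probabilities of every table with the same margins whose
    probability does not exceed that of the observed table.
    """
    import numpy as np

    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    rv = hypergeom(n, r1, c1)
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = rv.pmf(ks)
    p_obs = pmf[a - k_min]
    total = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    return min(1.0, float(total))
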