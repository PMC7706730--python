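# Methods

`mosaicsv` studies somatic mosaicism in clonally expanded cell populations:
when a single progenitor cell is grown into a clone and sequenced in bulk, a
structural variant (SV) present in the founding cell appears at ~50% allele
fraction, making events detectable that single-cell amplification would bury
in artifacts. The package implements the complete in-silico arm of that
study design — a hermetic clone-sequencing simulator, split/discordant-read
SV discovery with clone-to-clone somatic filtering, local assembly with
replication-model (template-switch) breakpoint resolution, pseudoreference
genotyping, a read-depth copy-number post-filter, and the timing, droplet
PCR and incidence statistics.

## The rearrangement model

A (possibly complex) SV allele is described as an ordered chain of oriented
reference segments that replaces a reference span (the *anchor*). This is
both the simulator's input language (`AltAlleleSpec`) and the resolver's
output (`RearrangementModel`): the two meet in `mosaicsv.rearrangement`,
which owns a single coverage arithmetic. Within the rearranged region,
reference bases covered by no chain segment are deletions, bases covered two
or more times are duplications, reverse-orientation local segments are
inversions, and segments from distal loci (>10 kb away, or other
chromosomes) are insertions. Every junction where the next segment does not
continue contiguously from the previous one is a replication-fork *template
switch*; the jump distance is the reference distance between donor end and
acceptor start (inter-chromosomal jumps are recorded but excluded from the
numeric spectra). The model's absolute size is |reference length − alternate
length| over the anchor span.

The base partition of the anchor region — deleted (coverage 0), replicated
footprint (covered by an interior segment), collinear (flank-only) — always
sums to the region length; this conservation identity is property-tested on
random chains. The replicated-fragment *size spectrum* lists interior
segment lengths themselves (including inter-chromosomal segments, which have
no footprint inside the region).

### Microhomology

The junction microhomology (MH) operator reports, for a donor→acceptor
junction, the larger of the left-side homology (the donor's last *m* bases
equal the acceptor template's preceding *m* bases) and the right-side
homology (the donor's continuation equals the acceptor's first *m* bases).
The convention is symmetric because junction placement is ambiguous by
exactly the homology length.

The simulator realizes a requested MH of length *m* by left-homology
editing: the *m* reference bases immediately upstream of the acceptor
breakpoint (in template orientation) are overwritten with the donor's last
*m* bases. These positions lie outside the alternate sequence, so genome and
reads remain self-consistent. One additional base on each side is forced to
differ so the measured homology is exactly *m* and junctions stay
left-aligned. `implant_sv` applies all edits through a conflict-checked
ledger, re-measures every junction with the MH operator afterwards, and
rejects alleles whose edits contradict each other. Because a germline SNP
sitting directly on a breakpoint would blur the truth coordinates, SNP panel
sites within MH+8 bp of any junction are pruned at implant time.

## The simulator

Each sample (clone, tissue bulk, or control) is a diploid population:
haplotype 1 is the reference plus homozygous SNPs; haplotype 2 additionally
carries heterozygous SNPs, the clone-private somatic SNVs, and the sample's
SV alleles. Fragments (normal insert, default 400 ± 50 bp, truncated at the
read length) are drawn from the two haplotypes in equal proportion; a
subclonal allele at cell fraction *f* re-sources overlapping haplotype-2
fragments from the reference haplotype with probability 1 − *f*, so junction
reads appear at allele fraction *f*/2 (0.5 for clonal events). Expected pair
count is coverage × genome length / (2 × read length).

Reads are projected onto the reference the way an aligner would report them:
the block with the largest overlap is the primary alignment (as BWA-MEM
would choose), bases extending past the junction become soft clips, reverse
blocks flip the clip sides and report the sequence in reference-forward
orientation, inter-chromosomal mates get inter-contig mate fields, and pairs
straddling a deletion show inflated insert sizes. Base errors are uniform
substitutions at 0.1% with no indels. Soft-clip positions are exact in this
emulation — a property the resolver exploits (below).

eccDNA alleles (a deletion whose excised span persists as a circle)
additionally emit fragments from the circular template, whose wrap-around
junction projects as reciprocally clipped reads at both deletion
breakpoints. MDA chimera artifacts are injected for `mda=True` samples as
fold-back (inverted, one-sided) junctions with a short duplicated span
within 1 kb and no reciprocal partner. Per-bin read depth is Poisson around
coverage scaled by the local copy number implied by the truth
(heterozygous deletion bins ×(1 − f/2), duplications ×(1 + f/2)), normalized
to a genome-wide mean of 2.0.

What the simulator does **not** model: aligner mismapping, PCR duplicates,
GC bias, indel errors, repeat-induced multimapping (genomes are i.i.d.
random sequence, so every 15-mer is effectively unique), chromatin- or
replication-timing-dependent SV placement, and MDA amplification bias beyond
the chimera junctions. Passing round-trip tests therefore demonstrate the
correctness of the workflow's logic under clean mappability, not calling
performance on real genomes.

## Discovery

A read is *abnormal* if it is soft-clipped by more than 30 bases, its insert
size exceeds the sample mean + 3 SD (estimated from ≥100 proper pairs), or
its mate maps to another chromosome. Soft-clip positions within 10 bp on the
same contig/side are clustered (median position, lower coordinate on ties);
clusters with fewer than 3 split reads are dropped. Candidate pairs are
typed by cross-matching clipped sequences against the partner locus at ≥90%
identity: right-clip + left-clip with forward continuation → DEL, the mirror
arrangement → tandem DUP, same-side clips matching the reverse strand → INV,
inter-chromosomal or unpaired candidates → BND. An unpaired candidate whose
clipped tail matches the nearby forward reference is rescue-typed as a
DEL/DUP junction (the partner cluster merely missed the 3-read floor); an
unpaired candidate matching the local reverse strand is an inverted
(one-sided) breakend — the MDA chimera signature.

Somatic filtering compares every clone against every other clone: a
comparison votes a call somatic iff the control shows zero supporting
abnormal reads at its breakpoints; calls voted in ≥80% of informative
(non-carrier) comparisons are retained, with clones sharing a locus reported
once as co-carriers. Same-type calls overlapping ≥50% reciprocally are
merged to a fixpoint (idempotent); same-sample calls with breakpoints within
1 kb are grouped single-linkage into complex SVs; groups containing a
one-sided inverted breakend adjacent to a duplication are flagged as MDA
artifacts (a fully reciprocal DEL+DUP pair is not flagged — that is the
excision-circle signature and is fused into a `CircularDnaEvent`).

## Assembly and resolution

Assembly is greedy overlap-layout-consensus: locus read pools are tiny
(tens of reads), so repeatedly merging the pair with the longest near-exact
suffix/prefix overlap (candidates from shared k-mers at half the minimum
overlap; ties broken toward the lexicographically smallest merged sequence;
mismatch columns resolved by read support) is simple and deterministic.
Contigs are aligned to the reference by exact 15-mer seeding on both strands
with maximal per-diagonal extension; isolated mismatches are crossed only
when the next five bases confirm, so sequencing errors cannot shift a
junction boundary. The best contig tiling is selected by weighted interval
scheduling (weight = length × identity) allowing up to 20 bp of overlap
between consecutive alignments; that overlap *is* the junction's
microhomology and is resolved by left-aligning the junction (trimming the
acceptor), which keeps recovered segment sizes exact.

Resolution is junction-wise rather than contig-wise, because interior chain
segments can be far longer than a read: every assembled contig contributes
directed (donor → acceptor) junction observations; boundaries are snapped to
soft-clip positions (exact breakpoint markers, robust to single-coverage
consensus errors, with chimeric assembly seams inside duplicated sequence
discarded for lacking clip support); each junction is oriented into its
left-homology-dominant form and paired with its synthesized mirror; and a
depth-first walk orders the junction classes into the chain that starts and
ends collinearly on the anchor contig, consuming each adjacency exactly
once. Junction loci exposed by the walk (including on other chromosomes)
are chased iteratively until the junction set closes.

When several walks close — the replication model is a hypothesis, and some
interpretations are genuinely equivalent (a distal inverted insertion
produces paired-end data identical to a genome-scale inversion plus a
duplication) — the package selects by, in order: (1) fragment support, the
number of junction-crossing read pairs that fit the reconstructed allele
with consistent mate orientation; (2) allele-forward traversal (walks using
the most left-aligned primary junction forms); (3) parsimony, the smallest
total rearranged footprint (anchor span + segment lengths); and (4) the
smallest total template-switch jump distance. This is the package's own
canonicalization convention for co-optimal chains.

The *explanation score* of a resolved model is the fraction of abnormal
reads in the ±2 kb neighborhood that align end-to-end (either strand,
≤2 edits) to the reconstructed allele; calls must exceed 0.8 strictly.

## Genotyping

The pseudoreference concatenates the resolved alternate allele with 2-kb
reference flanks; homozygous SNPs in the panel (ALT fraction ≥0.9 in ≥90%
of same-brain clones) are reverted to the reference base so they cannot
masquerade as ALT evidence, and every reversion is logged. A read counts for
an allele iff its best alignment (edlib, infix mode) beats the other allele
by ≥5 edits *and* crosses a diagnostic position — a chain junction on the
ALT side, an anchor breakpoint on the REF side; flank-only reads count for
neither. Presence ⇔ unique ALT reads > 0. For absent samples the allele
fraction is bounded above by 0.5/N, where N is the carriers' diagnostic read
capacity (the carrier's reads correspond to ~50% allele fraction, so one
read corresponds to 0.5/N). Carriers are classified subclonal when the
allele fraction is significantly below 0.5 (one-sided binomial test,
α = 0.01) or a heterozygous SNP inside the deleted region still shows both
alleles (two haplotypes persist where a clonal deletion leaves one).

The read-depth post-filter consumes 200-bp binned, mean-normalized copy
number. A deletion passes iff tissue CN ≥ 1.6, clone CN ≤ 1.4, difference
≥ 0.5, ≥60% of the other clones have CN ≥ 1.6, and the call is >1 Mb from
any reference gap. The duplication clauses are implemented as the mirror
image (clone > 2.6 strictly, tissue ≤ 2.4, ≥60% of other clones < 2.4): the
source description's "at least 2.4 in tissue" contradicts the direction of
its own deletion logic and is treated as a transcription slip, but the
literal reading is available via `dup_tissue_as_printed=True`. Region CN is
rounded to 9 decimals before comparison so decisions flip exactly at the
printed thresholds. Every failure lists the violated clause.

## Statistics

*Timing.* Somatic SNVs accumulate at `snv_rate` per day per progenitor
(default 5.1). Two clones sharing an SV diverged mean(n₁, n₂)/rate days
before harvest, where nᵢ are their private SNV counts; with the brain's
harvest age the event is placed in weeks postconception. Weeks are reported
both raw and rounded half-up. The worked example — 53 and 65 private SNVs —
gives 11.57 days ≈ 2 weeks, hence an origin of ~14 weeks postconception for
a 16-week harvest.

*Sensitivity.* The truth set is the ≥50% reciprocal-overlap intersection of
two independent bulk call sets; each clone's sensitivity is the fraction of
truth entries recovered at the same criterion, and equals plain recall when
the truth set covers every implanted event.

*ddPCR.* Copies per droplet follow λ = −ln(1 − k/n) per channel; the allele
fraction is λ_var/λ_ref. The 95% CI propagates the Wilson interval of each
positive-droplet fraction through the log transform and combines channels
as independent errors. The detection floor for mass *m* ng of input at
`pg_per_genome` (default 10 pg — the round value consistent with
40 ng → 4000 genome equivalents; the textbook diploid value is ~6.6 pg) is
1/(1000·m/pg) as a percentage: 0.025% at 40 ng.

*Incidence.* `fisher_exact_two_sided` enumerates all tables with the
observed margins and sums hypergeometric probabilities not exceeding the
observed one (with the conventional 1+1e-7 tie tolerance). For 4/41 vs 0/36
this gives p ≈ 0.1184; published analyses of the same comparison have
printed 0.1173, an unexplained tool-convention difference of ~1% that this
package does not reproduce by construction.

## Problem sizes and defaults

Round-trip validation uses 20 random complex alleles (1–5 segments of
50–2000 bp, 2–4 bp junction MH, deletions up to 2 kb) on 2×100 kb genomes at
30× with 150-bp reads — the smallest configuration in which 2-kb windows,
flanks, and distal segments (>12 kb from the anchor) all fit. The random
allele generator keeps segment boundaries ≥60 bp apart and local segments
clear of the anchor span: a segment overlapping the anchor boundary makes
the anchor placement itself ambiguous, and no convention could then match
an arbitrary labeling. The sensitivity scenario implants 100 germline
deletions (500–1500 bp) on 2×150 kb and compares two bulks and one clone.
Genotyping scenarios use 2×25 kb with 20 SV-free specificity samples.

## Known limitations

- The genotyping allele fraction is the raw unique-read ratio
  ALT/(ALT+REF), following the assay's definition. For simple deletions the
  REF allele exposes two breakpoint-spanning windows where the ALT allele
  has a single junction, so clonal carriers of large plain deletions read
  out below 0.5 (~0.3–0.45); balanced alleles (a deletion with inserted or
  inverted segments) measure ~0.5. Clonality calls for simple deletions
  should therefore lean on the deleted-region heterozygous-SNP criterion,
  which is unaffected.
- The resolver assumes each adjacency occurs once per allele: a chain
  repeating the *same* junction (e.g. an immediate triple tandem repeat of
  one segment) collapses to a single traversal.
- Observationally equivalent interpretations are reported via the
  canonicalization convention above, not enumerated; `walk_chain_all`
  exposes all co-optimal walks for callers who want them.
- Discovery sensitivity derives from clean mappability; real repeat-rich
  genomes would lower it and would require mapping-quality-aware filters the
  emulation has no need for.
- The CNV post-filter consumes externally binned depth; no mean-shift
  segmentation or GC correction is performed.
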