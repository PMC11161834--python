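# Methods

This note records the models, algorithms and numerical choices behind
`circsat`, and what the synthetic data do and do not establish.

## The measurement problem

An ectopic site (ES) in a human cell line carries, in order: an upstream
spacer, a 48-bp FRT recombinase site, a dTomato reporter, an Alu-like
repeat ending in a d(T)29 tail, a replication-origin cassette, the two
inverse-PCR primer sites flanking a non-B microsatellite insert, an eGFP
reporter, a second Alu, a TK cassette, a second (identical) FRT, a third
Alu and a downstream spacer. Replication stress at the microsatellite
produces double-strand breaks repaired by break-induced replication, whose
template switches excise and circularize mutagenized eccDNAs. Inverse PCR
amplifies only circles containing both primer sites; circular-consensus
sequencing returns each product, frequently as a tandem concatemer.

The pipeline's job is to turn those reads into: monomer PCR products;
ordered template-switch domains per monomer; the microhomology at every
junction, including the circle-closing one; and per-generation mutation
rates and substitution signatures computed over the domains.

## Synthetic data generator

The generator is first-class code, not a fixture: every downstream stage
is validated against its ground truth.

**Ectopic site.** Built from an ordered feature list; intervals tile the
contig exactly. The two FRT copies are byte-identical (the full 48-bp
site); the three Alu copies share one body (282 random bases ending in a
non-T, plus 29 T's). Feature sizes are desk-scale surrogates (reporters
~0.7–0.9 kb, origin cassette 0.42 kb, spacers 0.52 kb; ~6 kb total): large
enough that domains of a few hundred bp with several-hundred-bp switch
jumps fit comfortably, small enough that the full test suite runs in
seconds. The bases flanking each repeated copy are pinned pairwise distinct
for three positions on each side, so the maximal shared homology of a
repeat pair is the repeat itself and an aligner cannot creep past it on
chance matches.

**eccDNA structures.** A circle is an ordered list of domains (contig,
interval, strand) with one junction per domain (the molecule is circular).
At each junction the two donor loci must actually share the requested
microhomology; the circle realizes it once, and by convention the
homology bases belong to the *upstream* domain both in the assembled circle
and in the truth record. The random-structure sampler places each next
domain at an occurrence of the upstream domain's terminal k-mer, subject
to:

- *exact pinning*: the three flanking bases on each side of the shared
  block differ between the two loci, so the realized maximal homology
  equals the request exactly (and boundary recovery cannot drift);
- *minimum jump*: a same-contig switch must move ≥ 450 bp — a smaller jump
  is observationally indistinguishable from a plain deletion or
  duplication;
- *repeat avoidance*: junction endpoints keep ≥ 120 bp away from FRT/Alu
  copies (in the ES or planted in donor contigs), because an endpoint near
  a repeat lets an aligner bridge into the other copy. The circle-closing
  junction is exempt: it is repeat-mediated by design, normally through
  the two identical FRT copies (48 bp).

Unsatisfiable requests raise a generation error rather than degrading.

**Mutagenesis.** Event counts are Poisson with mean rate × length ×
generations, placed uniformly; deletion and insertion lengths are
geometric. The default rate presets are the measured per-clone columns
(e.g. (CAG)102 clone 10: mismatches 1.28e-6, deletion events 8.00e-6,
deleted nucleotides 8.75e-5, insertion events 7.15e-6, inserted
nucleotides 1.67e-5 per bp per generation over 200 generations; length
means are the per-event ratios C/B = 10.9 and F/E ≈ 2.3). Events drawn on
top of an earlier deletion tract are dropped (≈ 1% at these densities).
Generations default to 200 for the (CAG)/(ATTCT) presets and 150 for
G4/H3.

**Reads.** The amplicon runs from the forward-primer 5′ end around the
circle to the reverse-primer 5′ end; the gap between the 5′ ends (which
contains the microsatellite in the default layout) is unamplified. Reads
carry 1–8 tandem monomers; a small `spanning_fraction` (default 0.02)
rolls through the gap, emulating rolling-circle iPCR artifacts, in which
case the repeated unit is the full circle. Substitution errors are Poisson
per kb (default 0.1/kb, under the 0.2/kb circular-consensus control
bound); reads are emitted on a random strand. Circles whose primer sites
were mutated do not amplify and are counted, mirroring what iPCR would do.

**What the simulator does not emulate.** PCR length bias and chimera
formation, polymerase-specific error spectra, base-quality structure,
real host-genome repeat families beyond the planted Alu copies, eccDNA
copy-number/abundance, and any replication biochemistry. Conditions
(drug, knockdown) are emulated only as different parameter sets. Passing
tests therefore demonstrate correctness of the *computational* recovery
under controlled structure, not robustness to every artifact of real
libraries — for real data, the SAM/PAF import path exists precisely so a
production mapper can stand in for the internal aligner.

## Decatenation

Primer occurrences (forward, reverse, both reverse complements) are found
by semi-global edit-distance scanning (vectorized DP giving the best
distance for a window ending at every read position), with ≤ 2 edits by
default — at a ccs error rate < 0.2/kb, three edits in a 24-mer are
vanishingly rare. Overlapping candidates resolve by lower distance, then
leftmost. Reads are strand-classified by majority of hits and flipped so
the forward primer reads 5′→3′; a monomer spans a forward-primer start to
the end of the following reverse-complemented reverse primer. Terminal
fragments lacking one primer, inter-monomer gap sequence and
opposite-strand (ambiguous) regions are discarded and counted, so base
accounting is conservative and checkable. Specificity requires the six
bases 3′ of each primer to match the ES flanks exactly; deduplication is
exact string identity after normalization (only identical recombinants
collapse), keeping the first monomer by (read id, index).

## Split alignment and chaining

The internal aligner is exact-seed (k = 15) and extend. Seeds with more
than 12 occurrences are skipped (poly-T tails and microsatellite units far
exceed this; genuine repeat copies stay under it). Seeds cluster by
colinearity: same contig, non-decreasing target, query gap ≤ 100 bp (below
any plausible domain length, above any mutation-induced seed desert) and
diagonal drift ≤ 250 bp (absorbing indels). Each cluster is extended on
both sides by semi-global alignment whose path is walked with a local
score (+1 match, −2 mismatch, affine gaps 4 + 0.5/base) and an X-drop of
40: extension crosses ordinary indels but stops at template-switch
boundaries, where the pinned flanking bases guarantee an immediate score
drop. The chosen spans are finalized with a global edit-distance
alignment.

Because a minimal-unit-cost path can fragment one biological indel into
several runs interleaved with chance matches (inflating event counts
~3-fold at realistic deletion lengths), each local event cluster —
operations separated by match runs ≤ 15 — is re-aligned with affine gap
penalties (mismatch 4, gap open 6, extend 1; Gotoh, full traceback) and
re-represented canonically; ties left-align. Alignments are cross-checked
against `samtools mpileup` on the same SAM in the test suite. Boundary gap
operations are stripped so segments start and end on aligned bases.

Chaining maximizes total segment score minus double-counted query-overlap
bases over query-colinear subsets (DP; adjacent segments may overlap by ≤
300 bp, the microhomology allowance matching the ~300 bp maximum observed
overlap). Ties prefer fewer junctions, then leftmost target start; the DP
is verified exactly against exhaustive enumeration for ≤ 6 candidates.
After selection, the double-mapped homology is trimmed from the downstream
domain (upstream-owns-homology convention, same as the simulator truth).

Domains on a contig other than the ES are nonallelic; their copy direction
follows strand (coordinates increase p→q, so "+" is p→q). A nonallelic
call is verified if the domain's read sequence contains ≥ 1 25-mer absent
from both strands of the ES contig — this separates a genuine donor
segment from a misalignment of ES-shared sequence (the c-myc-style
ambiguity), and returns "indeterminate" below 25 bp.

## Junction microhomology

The overlap at a junction is the maximal block of read bases spanning the
junction that aligns exactly both to the reference continuation of the
upstream locus and to the reference preamble of the downstream locus —
shared donor homology realized once in the read. It is computed by
bidirectional per-base extension in reference space from the chain's
split point, so it is independent of how the aligner happened to split
the double-mapped region; an exhaustive brute-force oracle checks it on
randomized fixtures. Read bases matching neither flank are a nontemplated
insertion; a junction carries either an overlap or an insertion (when
both occur the larger feature classifies it, and both are recorded).

The circle-closing junction is identified as the junction between
ectopic-site domains with the maximal backward jump in ES coordinates —
the sealed fragment ends are the downstream-most domain end joined back
to the upstream-most domain start, which in iPCR geometry is always
traversed by the amplicon. Its mediating repeat is the annotated feature
(FRT/Alu) covering > 50% of the overlap, else "other"; a seal inside the
Alu d(T)29 tail is sub-annotated and the number of lost T's logged as the
reference run length minus the longest T run in the overlap.

`test_nonrandom` compares an overlap-length distribution against a seeded
random array (default: uniform integers on [0, max observed], seed 1729 —
the distribution of the original "random number array" is not specified,
so the null is recorded explicitly in every report). It returns the
two-sample Welch t statistic and, as the recommended primary result, a
label-permutation p-value on the absolute mean difference ((1 + #extreme)
/ (1 + n_perm)); with a degenerate zero-variance input the t-test is
flagged inapplicable and the permutation result still returned. Type-I
error is calibrated to nominal 0.05 in the acceptance suite.

## Mutation quantitation

Pileups are restricted to template-switch domain intervals. A deletion
event is one maximal run of contiguous deleted reference bases, counted
once at its start column; an insertion event is one contiguous inserted
string anchored between reference positions; mismatches at N are excluded
and counted separately. The rate table divides totals by aligned_bp ×
generations, where aligned_bp is the total of reference bases covered by
analyzed domains (deduplicated monomers) — the natural reading of "within
template switching domains". D = C/B and G = F/E with NA propagation; H
is computed literally as A + C + F per its row label. Per-kb deletion
metrics omit the generation normalization. The per-read threshold removes
reads with (mismatches + indel events) per aligned kb below 2 by default;
thresholding is per-read, rates are pooled. Substitution signatures fold
every contexted mismatch onto the 96 pyrimidine-centered channels
(6 classes × 16 trinucleotide contexts); purine-reference calls are
recorded at the reverse-complement context, and edge/N-context calls are
skipped and counted.

## Problem sizes and determinism

Default test fixtures use a ~6-kb site, circles of 1–3 domains of 0.12–0.8
kb, and tens to hundreds of reads; rate-recovery checks use ~6400
single-monomer circles (~5000 surviving monomers, ~15 Mb aligned).
Everything is driven by `numpy` generators derived from one integer seed
(all derived seeds < 2^31); identical seeds give byte-identical FASTQ,
truth and reports.

## Known limitations

- The internal aligner targets desk-scale hybrid references (an ES contig
  plus small donor surrogates); it builds a full k-mer index in memory and
  makes no whole-genome performance claims. Real-genome runs should import
  BWA-MEM/minimap2 alignments via SAM/PAF.
- PAF import preserves coordinates and run-length edit operations but not
  mismatch base identities (PAF carries no sequence), so signatures need
  SAM-with-sequence or internal alignment.
- Junctions placed inside long homopolymers or between near-identical
  repeat copies are intrinsically ambiguous; the simulator avoids creating
  them except where the ambiguity is the point (repeat-mediated closure),
  and real-data calls in such contexts should be treated as
  lower-confidence.
- Monomers are analyzed independently; there is no within-read consensus
  polishing, and mutations/kb below the sequencing error rate are not
  deconvolved from it.
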