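# circsat

Analysis of extrachromosomal circular DNAs (eccDNAs) generated by non-B
microsatellites, from inverse-PCR circular-consensus long reads.

Expanded microsatellites that fold into non-B DNA — (CAG)n hairpins,
G-quadruplexes (G4), H-DNA triplexes, AT-rich unwound DNA — stall
replication forks and are repaired by error-prone break-induced replication
(BIR). One product of this repair is a population of highly mutagenized
eccDNAs assembled from "template-switch domains": read segments that are
contiguous in the molecule but map to noncontiguous loci of the ectopic
integration site (ES) or to nonallelic chromosomes, joined at short
microhomologies and sealed into a circle through repeated sequence (the
48-bp FRT site, Alu elements and their d(T)29 tails). Inverse PCR (iPCR)
with outward-facing primers amplifies only the circular molecules; long
circular-consensus sequencing then reads each PCR product, often as a
tandem concatemer of the amplicon.

`circsat` implements the computational side of that experiment as a
reusable, fully testable pipeline:

- **refsim** — a synthetic-data generator: parameterized ectopic-site and
  donor contigs (reporters, origin cassette, microsatellite insert, FRT
  pair, Alu-like repeats, primer sites), eccDNA structures with exactly
  realizable junction microhomologies, per-generation mismatch/indel
  mutagenesis, iPCR concatemer reads with a background error rate, and
  complete ground truth. Includes a canonical G4 consensus scanner
  ((G)3(N)1–7(G)3(N)1–7(G)3(N)1–7(G)3, both strands).
- **decat** — decatenation of concatemer reads into monomer PCR products by
  approximate primer recognition, orientation normalization, the
  ectopic-site specificity filter (≥ 6 reference bases 3′ of each primer)
  and exact-sequence deduplication.
- **segmap** — seed-and-extend split alignment of monomers against a hybrid
  reference (ES contig + host contigs), affine-gap event consolidation,
  dynamic-programming chaining into query-colinear template-switch domains,
  intra-ES vs nonallelic classification and donor-unique k-mer
  verification; SAM/PAF/BED interchange.
- **junctions** — microhomology overlap at every template-switch junction
  (maximal read block matching both donor loci, measured in reference
  space), nontemplated-insertion calls, circularization-junction detection
  with FRT/Alu mediator annotation, overlap-length distributions, and a
  nonrandomness test (Student's t against a seeded random array, plus a
  permutation test).
- **mutquant** — per-position pileups over template-switch domains and the
  mutation metrics: rows A–H of the per-generation rate table
  (mismatches/bp/generation, deletion and insertion events and nucleotides,
  per-event ratios, and the A + C + F total), deleted-bases/kb and
  deletion-events/kb, the 2 mutations/kb per-read threshold, and 96-channel
  pyrimidine-centered trinucleotide substitution signatures.
- **cli / pipeline** — orchestration (`simulate → decat → map → junctions →
  mutquant`), a machine-readable run report with count conservation checks,
  condition comparison, and deterministic fixture bundles.

## Worked example

Simulate six eccDNAs from a (CAG)102 ectopic site, mutagenized at the
measured per-clone rates, then run each stage:

```
circsat simulate --preset CAG102 --circles 6 --reads 2 --domains 3 \
    --rates CAG102_c10 --seed 4 --outdir sim
circsat decat --reads sim/reads.fq --es sim/reference.fa \
    --es-contig ES_CAG102 --outdir decat
circsat map --monomers decat/monomers.fa --reference sim/reference.fa \
    --es-contig ES_CAG102 --outdir map
circsat junctions --monomers decat/monomers.fa --reference sim/reference.fa \
    --es-contig ES_CAG102 --features sim/features.bed --outdir junc
circsat mutquant --monomers decat/monomers.fa --reference sim/reference.fa \
    --es-contig ES_CAG102 --generations 200 --outdir mq
```

which prints

```
wrote 10 reads from 6 circles to sim
monomers=12 nonspecific=0 duplicates=7 unique=5
mapped=5 unmapped=0
junctions=15 circularization=5
aligned_bp=17826 deleted_bases_per_kb=14.64 deletion_events_per_kb=1.74
```

Ten reads survive (circles whose primer sites were hit by a mutation do not
amplify), splitting into 12 monomers of which 5 are unique after
deduplication; every monomer chain is recovered and each carries one
circularization junction. `junc/junctions.tsv` shows the per-junction
calls — the circle-closing junction of the first molecule reads

```
chain     class            overlap_len  overlap_seq                                       mediating_repeat
ecc0/0/0  circularization  48           GAAGTTCCTATTCCGAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC  frt
```

i.e. a 48-bp overlap that is exactly the FRT site: the circle was sealed by
homologous recombination between the two FRT copies. `mq/rates.tsv` holds
the per-generation rate table (rows A–H); on this small run the deletion
rate works out to 8.7e-06 events/bp/generation with 8.4 deleted
nucleotides per event, within sampling error of the injected (CAG)102
clone-10 parameters (8.0e-06 and 10.9).

The same pipeline runs end-to-end on files with `circsat run --reads r.fq
--reference hybrid.fa --es-contig ES ... --outdir out`, producing
`report.json`, `domains.paf`, `junctions.tsv`, `rates.tsv` and
`signature.tsv`; alignments from an external mapper can be imported from
SAM or PAF through `circsat.segmap.read_sam` / `read_paf` instead of the
internal aligner.

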