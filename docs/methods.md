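# Methods

This note documents the models, conventions and numerical choices behind
`plastedit`, and what its validation does and does not demonstrate.

## The measurement model

Plastid C-to-U editing is observed through strand-specific RNA-seq as a
C→T substitution on the transcribed strand of an otherwise-matching
alignment. Two facts shape the whole design:

1. **Editing is partial.** At a site with efficiency *e*, each sequenced
   transcript molecule independently carries the edit with probability *e*;
   read counts at a site are therefore binomial. Efficiency is estimated as
   edited reads / total mapped reads, pooled over a condition's replicates.
2. **Sequencing errors mimic low-efficiency editing.** The filter cascade
   (depth ≥ 10, ≥ 2 edited reads per replicate, support in ≥ 2 replicates)
   exists to separate genuine partial editing — reproducible across
   biological replicates — from errors, which are not.

Strand matters throughout: pileups are stored in *transcribed-strand
space*, i.e. a minus-strand alignment contributes the complement of its
forward-genome base, so "reference C, alternate T" always reads as the
transcript does. Genic positions are evaluated on the annotated transcript
strand only; intergenic positions on both strands.

## Coordinates and annotation

External coordinates are 1-based inclusive. The genome is circular; reads
and alignments may span the origin and wrap, but gene models themselves
are required not to (and must be colinear — trans-spliced genes such as
real-plastome *rps12* are out of scope).

Gene position is the 1-based offset in the spliced CDS counted from the
gene's own 5′ end; codon offset is `((gene_position − 1) mod 3) + 1` and
must coincide with the uppercase base of a printed codon string such as
`cCa`. Translation uses NCBI table 11 (plastid/bacterial); for every codon
in the reference table this coincides with the standard code. An effect is
*silent* iff the reference and edited codons translate identically; a
*start gain* is ACG→AUG at codon 1. A site inside a gene's exons but
outside its CDS is classified 5′UTR or 3′UTR by its side relative to the
CDS in transcription direction; between exons it is an intron; outside all
genes, intergenic. The region partition is total; 3′UTR is supported even
though the reference table happens to contain none.

### Reference-table consistency checking

`annotate_fixture` recomputes, for each of the 58 coding rows of the
packaged table, the codon offset and the amino-acid change, and compares
them with the printed columns. Missense and start-gain rows are compared on
the exact residue string. Synonymous rows are compared on *synonymy* of the
recomputed change rather than the residue letter: the letter is redundant
for a silent edit, and one printed silent row (rps3, codon `uuC`, printed
`I>I`) carries a residue letter inconsistent with its own codon (UUC→UUU is
F>F). The table is shipped verbatim; the checker validates the row as
silent without endorsing the residue letter.

### A known discrepancy the package reports rather than resolves

Counting ndhB coding rows that are `+` in coconut, rice and maize yields
five conserved-in-all sites, while prose descriptions of the same data
claim six; the sixth candidate (ndhB-14) is `?` in all three species. The
conservation module computes from the table and classifies ndhB-14 as
`unresolved`. `unresolved` itself is an addition to the pattern vocabulary:
a row with no `+` but untested (`?`/`NA`) cells is neither conserved nor
provably focal-specific, and forcing it into either label would overstate
the evidence.

## The synthetic-data generator

The generator emulates what the analysis assumes about deep total-RNA
plastid sequencing, at desk scale:

| parameter | default | rationale |
|---|---|---|
| genome_length | 15,000 bp | large enough for 20 genes plus intergenic space; runs in seconds |
| gene_count | 20 | genes on both strands, ~15% with one intron |
| replicates | 4 + 4 | the reference design: four fronds, four turions |
| mean_coverage | 200× per strand per replicate | scaled down from the ~1,000× of real plastid total-RNA data; raiseable by flag |
| read_length | 100 bp | typical short-read length |
| error_rate | 0.001 | typical post-QC Illumina substitution rate |
| low_quality_read_fraction | 0.05 | reads built to fail the QC rule (mean Q < 20 or length < 70) |

Reads are single-end contiguous genomic windows from **both strands
everywhere**. This reflects pervasive, polycistronic plastid transcription
and the fact that total-RNA libraries retain unspliced precursors — which
is precisely why intron and intergenic editing sites are observable at all.
Reads do not splice; coverage is uniform rather than gene-dependent;
rRNA contamination and the inverted-repeat duplication of real plastomes
are not modeled. Editing is drawn per read per covered site as
Bernoulli(site efficiency for the read's condition) on the transcribed
strand only.

**Error model.** Every base receives a Phred quality from a two-component
profile (Q40 background with a thin Q7 tail) and is miscalled with
probability `10^(−Q/10)`, substituting uniformly among the three other
bases; the tail weight is solved so the mean per-base substitution rate
equals `error_rate` exactly. Errors are thus position-uniform but, as in
real sequencers, concentrated in bases that announce their own
unreliability. The pileup correspondingly applies the samtools-default
minimum base quality of 13. This pairing is what makes "no false calls at
default thresholds" a property of the method rather than of luck: with
quality-blind errors at 0.1% and quality-blind counting, a 15 kb genome at
200× per replicate would be expected to produce a fraction of an
error-driven call per run, and the zero-false-positive validation below
would be a coin flip. No indels are simulated; the analysis concerns
substitutions only.

Determinism: all randomness flows from `numpy.random.default_rng` seeded
with `(seed, stage-constant, condition, replicate)`; identical
configuration and seed reproduce genomes, truth tables and FASTQ files
byte-for-byte.

## Alignment acquisition

For simulated data the aligner is replaced by provenance placement: each
FASTQ header carries the read's true origin and strand, and placement
verifies the read against the genome, treating reads above 10% divergence
or with malformed tags as unmapped. For real data, single-end SAM is read
through pysam; FLAG 0x10 sets the strand, soft-clipped bases are excluded,
paired-end records are rejected. No mapping-quality filter is applied
beyond read QC (mean Phred ≥ 20, length ≥ 70, both inclusive), and no BAQ
recalibration is performed.

## Statistics

* **FPKM** is `fragments · 10⁹ / (exon_length · total_mapped)`; with
  single-end data a fragment is a read. Reads are assigned to every
  strand-matched gene whose exons they overlap.
* **Differential expression** uses Welch's *t* on log₂(FPKM+1) across
  replicates (the simplest defensible replicate-level test; exposed as the
  place to substitute another), BH-FDR, and flags only
  |fold change| > 2 **and** FDR < 0.05. Fold change is computed on
  condition-mean FPKM with guarded division: it is undefined when either
  mean is zero, and an undefined fold change never flags.
* **Differential editing** uses Pearson's χ² with 1 df and *no* continuity
  correction on per-condition pooled counts — at plastid depths Yates'
  correction is negligible, and the plain statistic is the convention;
  a flag enables BH correction across sites, but raw per-site significance
  is the default. Degenerate tables (a zero row or column margin) return
  (statistic 0, p = 1) with a warning instead of dividing by zero. The
  statistic is computed from the closed form
  `n(ad−bc)²/(r₁r₂c₁c₂)` and is cross-checked in tests against brute-force
  Σ(O−E)²/E and against scipy's uncorrected contingency test.
* **Sites edited in all reads** (100% efficiency) are still editing calls,
  not genomic SNVs, because the reference is the plastome DNA assembly;
  the caller logs this caveat.

## Conservation conventions

Shared-site fractions count rows with state `+` over rows that are
coding-region sites with non-`NA` state; intron and other non-coding rows
are excluded from the denominator. This is the convention under which the
packaged table reproduces its published ndh-family counts (21/26, 11/26,
10/26) exactly. The `-` state requires an assayed editome; without one, a
C is always `?` — the distinction is evidential, not sequence-based.
Phylogeny is accepted as a user-supplied ordering/tree; the package never
infers trees.

## Validation, and its limits

The test suite validates parameter recovery under the generator's own
assumptions: at 200× with 4+4 replicates and 0.1% error, all 66 implanted
sites (efficiencies 6–100%) are recovered with zero false positives and
mean absolute efficiency error under 1 percentage point, and the χ² null
simulation's false-positive rate sits at the nominal 5%. Passing these
says the *inference machinery* is correct and well calibrated; it does not
certify performance on real libraries, whose coverage is non-uniform,
whose errors are context-dependent, and whose strand protocols leak.
The caller's thresholds (depth ≥ 10, ≥ 2 edited reads, ≥ 2 replicates) are
exposed as flags precisely because real data may warrant stricter settings.

Problem sizes used by the shipped validation (15 kb genome, 200×, three
seeds for recovery; depth-500 null with 1,000 sites) were chosen so the
whole suite completes in about a minute on one core while keeping every
binomial approximation comfortably in its asymptotic regime.
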