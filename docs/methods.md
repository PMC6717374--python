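# Methods

## Classification model

**Single base substitutions.** Every SBS is re-oriented so that the mutated
base of the Watson-Crick pair is reported as a pyrimidine: when the VCF/MAF
reference base is a purine, the reference allele, alternate allele and
flanking context are reverse-complemented together. With no context this
gives the six substitution classes; with one or two flanking bases each side,
the 96 trinucleotide and 1536 pentanucleotide channels. Prefixing the
transcriptional strand label (below) yields 24, 384 and 6144 channels. The
pipeline accumulates at the strand × pentanucleotide level and derives every
coarser matrix by summation.

**Doublet base substitutions.** A DBS has two equivalent renderings
(reference strand and reverse complement). The canonical rendering is the
one with the larger total pyrimidine count over the ref and alt doublets;
exact ties are broken deterministically by the lexicographically smaller
reference doublet, then alternate doublet (A<C<G<T). Grouping all 16 × 9
ordered doublet substitutions by reverse-complement equivalence yields 78
classes; the canonical table is generated from this rule at import, not
hand-entered. The published convention resolves ties by an unstated
selection, so tie classes (e.g. the `AA:TT>CC:GG` family) may carry the
mirror name here; the partition into 78 classes is identical either way.
Adding one flanking base each side gives 16 tetranucleotide contexts per
class (78 × 16 = 1248); flanks are reverse-complemented and swapped together
with the doublet. Note the 1248 context channels are defined per canonical
class, not by re-deduplicating tetranucleotides: a full reverse-complement
dedup of all tetranucleotide events would give 1176 classes because
palindromic doublets with mirrored flanks coincide.

**Indels.** Pure insertions/deletions are classified by motif length
(1, 2, 3, 4, 5+), repeat context and microhomology:

* length 1: a homopolymer event named by the pyrimidine partner of the base
  (C or T), sized by the run length — deletions count the deleted base
  (sizes 1–6+), insertions count existing bases only (0–5+);
* length ≥ 2 with at least one full extra motif copy adjacent (or any
  insertion): a repeat event sized by the number of contiguous exact motif
  copies tiling the reference on *both* flanks (deletions include the
  deleted copy, so their size is ≥ 1);
* deletions with exactly one copy (the deleted one) whose motif partially
  overlaps a flank: a microhomology event sized by the longest proper prefix
  of the motif matching immediately 3' of the deletion or proper suffix
  matching immediately 5' (max of the two, 1–5+, structurally < motif
  length). Insertions are never classified as microhomology. Repeat takes
  precedence over microhomology: with a full extra copy present the event is
  a repeat by construction.

This yields exactly 83 channels. Events combining deletion and insertion at
one locus (complex indels) have no channel; they are tallied in the run log.

**Alignment invariance.** Callers may place an indel anywhere within a
repeat tract (and either side of a microhomology). Events are left-aligned
against the reference (shifting position and rotating the motif) before
classification, and both flanks are scanned, so every equivalent
representation maps to one channel. One printed example sequence in the
source material is typographically garbled ("ATTACA[GGCGC"); the
reconstruction `ATTACAACAGGCGC` is forced by the accompanying description of
two adjacent `ACA` copies and is what the tests use.

## Transcriptional strand bias

Each genome position carries one of four states derived from the union of
annotated gene footprints: non-transcribed, gene on the reference strand,
gene on the opposite strand, or bidirectional (covered by genes on both
strands). Same-strand overlapping genes collapse into a footprint union;
intron/exon structure is irrelevant to the state (exons are used only for
exome-mode subsetting). Labels: mutations outside footprints are `N`;
bidirectional regions give `B`; otherwise a pyrimidine-oriented event whose
pyrimidine strand is the coding (reference) strand of the gene is
untranscribed `U`, else transcribed `T`. Doublets and indels can only be
oriented when the reference doublet/motif is a pure pyrimidine or pure
purine stretch; mixed-composition events inside transcribed regions are
`Q` (unknown). For doublets whose canonical notation reads the purine strand
(a tie-break artefact) the flip flag is inverted so the label still tracks
the physical pyrimidine strand. The strand state of a multi-base event is
taken at its first affected reference base (after left-alignment), a
boundary convention that matters only for events straddling a footprint
edge.

The strand-bias statistic is not prescribed by the published method beyond
"FDR-corrected significance"; the minimal defensible instantiation used here
is an exact two-sided binomial test of T vs U counts against p = 1/2 per
channel core per sample (B/N/Q counts excluded, empty channels skipped),
with Benjamini-Hochberg adjustment within each (sample, scheme) family.

## Matrix inventory and collapse chains

The finest level of each class is accumulated while streaming one
chromosome at a time (one encoded chromosome resident in memory), then
collapsed:

    SBS-6144 → SBS-1536 → SBS-96 → SBS-6
             → SBS-384  → SBS-24 → SBS-6
    DBS(strand × context) → DBS-1248
                          → DBS-186 → DBS-78
    ID-415 → ID-83 → ID-28      (ID-8628 → ID-83 as a cross-check)

Fourteen matrices are written per run: six SBS, four DBS, four ID. SBS
events whose ±2 bp window leaves the chromosome or contains N are excluded
from the context matrices but still counted in SBS-24/6; likewise doublets
lacking a flank fall back to DBS-186/78. These exclusions are recorded in
the run log, so every collapse conserves column sums up to the ledger.

Channel sets whose composition the published method names but does not
enumerate are derived here from the stated rules and their cardinality is
reported, not asserted:

* **DBS-186 name**: the rule-derived strand-labeled class set has
  36 orientable classes × {T,U,B,N} + 42 unorientable × {N,Q} = 228
  channels (the strand-labeled context matrix analogously has 228 × 16).
  The conventional matrix names are kept for the files.
* **ID-28**: a documented reconstruction — kind × length class
  {C, T, 2, 3, 4, 5+} × a small/large split at the middle size bin (24
  cells) plus deletion-microhomology cells per length class (4), exactly 28.
* **ID-8628 name**: homopolymer/repeat channels with motif length ≤ 4 are
  extended by the canonical motif (lexicographically smaller of motif and
  reverse complement); microhomology and 5+ channels pass through. The
  derived set has 2183 channels.

## Input handling

VCF (via pysam; one file per sample named `<sample>.vcf`, or multi-sample
with genotype columns) and MAF (via pandas; `Tumor_Sample_Barcode` as the
sample) are normalized identically: alleles upper-cased, shared
leading/trailing bases stripped (MAF `-` means an empty allele), positions
converted to the first affected base (for insertions, the base after which
the insertion occurs). Duplicate identical records within a sample are
counted once. Two same-sample SBS records at consecutive positions merge
into one doublet by default (disable with `merge_dbs=False` /
`--no-dbs-merge`); runs of three or more adjacent SBS records are left
unmerged with a logged notice, since multi-base substitution semantics are
undefined in this classification. Records failing the reference-allele
check, containing N alleles, or on chromosomes absent from the build are
dropped and counted. Chromosome names are normalized (`chr` prefix stripped,
`M` → `MT`). BED regions are 0-based half-open; exome mode uses the exon
intervals stored at genome-encoding time. Indels longer than 100 bp are
classified normally (5+ bin) but logged, as "small" conventionally means
under 100 bp.

## Reference encoding

Each chromosome is stored as a flat uint8 array: low three bits base
(A=0, C=1, G=2, T=3, N=4 — any IUPAC ambiguity code encodes as N), next two
bits the strand state. One `<chrom>.bin` file per chromosome plus a JSON
manifest and copies of the footprint/exon tables constitute an installed
build. Annotation formats: a refFlat-like TSV (chrom, strand, txStart,
txEnd, exonStarts, exonEnds; 0-based half-open) or GTF. Public coordinates
are everywhere 1-based inclusive; internal arrays 0-based.

## Synthetic data

The fixture generator emulates a multi-sample somatic study at toy scale:
by default three chromosomes of 20/15/12 kb (a human-naming 25-chromosome
layout is available), four samples, and per sample 40 substitutions, 4
adjacent-SBS pairs, 10 doublets, 10 homopolymer indels, 10 repeat-tract
indels, 6 microhomology deletions and 2 complex indels — enough events per
family for every matrix to be exercised while a full run stays below a
second. Engineered loci (homopolymer runs of 4–8, primitive repeat units of
2–4 bases × 2–4 copies, microhomology cassettes of motif length 3–5) are
insulated by guard bases chosen so the constructed repeat counts and overlap
lengths are exact, and recorded in a manifest; a configurable fraction of
deletions is emitted right-aligned to exercise normalization. Annotations
place forward, reverse and (optionally) overlapping gene pairs, so all
strand states occur. All randomness flows from a single seed; output is
byte-deterministic.

What the generator does *not* emulate: realistic mutation rates or
signature-shaped spectra, sequencing artefacts, clustered mutations beyond
the engineered doublets, multi-allelic sites, or low-complexity genome
composition (background sequence is i.i.d. uniform). Passing tests therefore
demonstrate classification correctness and bookkeeping on well-formed
catalogues, not robustness to caller-specific quirks beyond the
representation variants generated.

The naive oracle classifies one mutation at a time directly from FASTA text
and raw annotation intervals, with independently written orientation,
repeat-scanning and strand logic — no byte encoding, no caching. Tests
require exact agreement between the oracle and the optimized pipeline on
≥10,000 random events (substitutions including chromosome edges, doublets,
deletions of 1–6 bases, insertions of random motifs).

## Numerical and formatting choices

Matrices are integer TSVs (`MutationType` column plus one column per
sample, UTF-8, LF), channels in a fixed documented order (substitution
blocks C>A…T>G with alphabetical contexts; canonical doublet classes sorted
lexicographically; indel channels homopolymer → repeat → microhomology;
strand labels T, U, B, N(, Q) within each core). Two runs over identical
inputs are byte-identical. Problem sizes in tests (kilobase chromosomes,
hundreds of events per run, 10⁴ oracle comparisons) were chosen so the whole
suite exercises every code path in seconds while leaving counts large enough
for the conservation and strand-bias checks to be non-trivial.

## Known limitations

* The DBS tie-break and the ID-28/ID-8628 compositions are deterministic
  reconstructions of unpublished tables; channel *partitions* and
  cardinalities 78/83/415 are guaranteed, exact tie-class naming and the
  186/28/8628 compositions are this package's own.
* Bidirectional-overlap semantics for genes nested on opposite strands
  follow footprint unions; positions inside a gene on one strand and
  another gene's intron on the other are BIDIRECTIONAL.
* The FILTER column of VCFs is ignored; genotype-quality-aware filtering is
  a caller concern.
* No parallel execution; the memory contract (one chromosome resident) is
  the optimization target, not wall-clock parity with any benchmark.
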