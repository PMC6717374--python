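# mutmat

Mutational-matrix generation for small somatic mutational events.

Cancer genomes carry somatic mutations imprinted by the mutational processes
that shaped them. Before any mutational-signature analysis (which is a matrix
factorization), the catalogue of each tumour's mutations must be transformed
into a matrix of counts over a fixed set of **mutation channels**. `mutmat`
performs that transformation for all three classes of small mutational
events, for people who analyse somatic variant catalogues (VCF/MAF) and need
channel matrices, strand-bias statistics and spectrum plots:

* **SBS** — single base substitutions, reported by the pyrimidine base of the
  mutated Watson-Crick pair, with 0/1/2 bases of flanking context and a
  transcriptional strand label: SBS-6, SBS-24, SBS-96 (the standard
  trinucleotide classification, e.g. `A[C>A]G`), SBS-384, SBS-1536, SBS-6144.
* **DBS** — doublet base substitutions, canonicalized to the rendering with
  the most pyrimidines (e.g. `AA>GT` ≡ `TT>AC`): DBS-78, the strand-labeled
  DBS-186, the tetranucleotide-context DBS-1248, and its strand-labeled
  extension.
* **ID** — small insertions and deletions classified by length, repeat-unit
  count, homopolymer run length and microhomology (e.g. deleting one `ACA`
  from an `ACAACA` tract is `3:Del:R:2`; deleting `TAGTC` next to a `TAGT`
  overlap is `5+:Del:M:4`): ID-83 with its collapsed (ID-28), strand-labeled
  (ID-415) and sequence-extended variants.

A default run emits **fourteen matrices** (TSV, channels × samples). The
reference genome is pre-encoded one byte per base (base identity plus a
two-bit transcriptional-strand state from the union of gene footprints), so
classification streams one chromosome at a time with constant-time context
and strand queries. Transcribed/untranscribed counts per channel are tested
with an exact two-sided binomial test and Benjamini-Hochberg FDR correction.
A synthetic-data module generates genomes with engineered repeat,
homopolymer and microhomology loci, annotations with forward / reverse /
bidirectional / intergenic regions, per-sample VCFs and a ground-truth
channel table, plus a naive FASTA-slicing oracle classifier used to
cross-check the optimized pipeline.

Out of scope by design: variant calling, signature extraction, copy-number /
structural-variant classification, and downloading reference genomes.

## Worked example

```python
from pathlib import Path
from mutmat import (FixtureSpec, make_genome, make_catalogue,
                    encode_genome, generate_matrices)

root = Path("scratch/examples/run")
spec = FixtureSpec(seed=7)                       # 3 chromosomes, 4 samples
genome = make_genome(spec, root / "genome")
cat = make_catalogue(spec, root / "genome", root / "catalogue")
build = encode_genome(genome["fasta"], genome["annotation"], root / "build")
result = generate_matrices("demo", cat["vcfs"], build, root / "output")
print(result["matrices"]["SBS6"].to_string())
```

prints

```
              S1  S2  S3  S4
MutationType
C>A            3   7  12   7
C>G            7   6   5   5
C>T           10   6   3   9
T>A            5   8   5   7
T>C            9   4   8   9
T>G            6   9   7   3
```

— the six-class substitution spectrum of each synthetic sample (each cell is
a mutation count; column sums agree with every finer SBS matrix of the same
run). `result["paths"]` lists the fourteen matrix files under
`output/SBS|DBS|ID/`, and `result["stats"]` is the drop/exclusion ledger
(reference mismatches, complex indels, context-unavailable events).

The scripts in `examples/` walk through each capability: reference encoding
and queries, matrix generation, strand-bias testing, plotting (including the
ten-panel per-sample portrait), and the classic indel worked examples. A thin
CLI mirrors the library: `mutmat install`, `mutmat matrices`, `mutmat plot`,
`mutmat fixtures`.

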