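"""Install (byte-encode) a small reference genome and query it.

Builds a two-chromosome FASTA with one forward-strand gene, encodes it, and
asks for base context and transcriptional strand state at a few positions.
"""
from pathlib import Path

from mutmat import encode_genome

out = Path("scratch/examples/reference")
out.mkdir(parents=True, exist_ok=True)

fasta = out / "genome.fa"
fasta.write_text(">1\nATTACAACAGGCGC\n>2\nGGTTCCAGGACCAA\n")
annotation = out / "genes.tsv"
# chrom  strand  txStart(0-based)  txEnd  exonStarts  exonEnds
annotation.write_text("2\t+\t2\t10\t2,8\t5,10\n")

build = encode_genome(fasta, annotation, out / "build", name="demo")
print("chromosomes:", build.chromosomes)

# the trinucleotide context around chromosome 1 position 4 (1-based)
print("context(1, 4, flank=1) =", build.context("1", 4, 1))
# a window running off the chromosome end is unavailable
print("context(1, 1, flank=1) =", build.context("1", 1, 1))
# strand state: inside the + gene vs intergenic
print("strand_state(2, 5)  =", build.strand_state("2", 5).name)
print("strand_state(2, 12) =", build.strand_state("2", 12).name)

# Expected: context TAC around the mutated base; None at the edge;
# GENE_ON_REFERENCE_STRAND inside the gene footprint, NONTRANSCRIBED outside.
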