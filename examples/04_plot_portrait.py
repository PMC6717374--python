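"""Spectrum plots: one scheme, and the ten-panel per-sample portrait."""
from pathlib import Path

from mutmat import (
    FixtureSpec, encode_genome, generate_matrices, make_catalogue,
    make_genome, plot_matrix, plot_portrait,
)

root = Path("scratch/examples/plots")
spec = FixtureSpec(seed=7)
genome = make_genome(spec, root / "genome")
catalogue = make_catalogue(spec, root / "genome", root / "catalogue")
build = encode_genome(genome["fasta"], genome["annotation"], root / "build")
result = generate_matrices("demo", catalogue["vcfs"], build, root / "output")

p1 = plot_matrix(result["matrices"]["SBS96"], "SBS96", "S1", root / "S1.SBS96.pdf")
p2 = plot_matrix(
    result["matrices"]["ID83"], "ID83", "S1", root / "S1.ID83.pdf", percentage=True
)
p3 = plot_portrait(result["matrices"], "S1", root / "S1.portrait.pdf")
for p in (p1, p2, p3):
    print("wrote", p)

# S1.SBS96.pdf: 96 bars colored by substitution class (counts).
# S1.ID83.pdf:  83 bars, heights in percent (summing to 100).
# S1.portrait.pdf: all ten plottable classifications on one page.
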