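from pathlib import Path
from types import SimpleNamespace

import pytest

from mutmat import FixtureSpec, encode_genome, make_catalogue, make_genome


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """One synthetic study shared by the suite: genome + annotation +
    catalogue + installed build."""
    root = tmp_path_factory.mktemp("world")
    spec = FixtureSpec(seed=11)
    genome = make_genome(spec, root / "genome")
    catalogue = make_catalogue(spec, root / "genome", root / "cat")
    build = encode_genome(
        genome["fasta"], genome["annotation"], root / "build", name="fixture"
    )
    return SimpleNamespace(
        spec=spec, root=root, genome=genome, catalogue=catalogue, build=build
    )


@pytest.fixture
def write_build(tmp_path):
    """Factory building tiny ad-hoc genomes: pass {chrom: seq} and optional
    annotation lines (chrom, strand, txStart0, txEnd, exonStarts, exonEnds)."""
    counter = {"n": 0}

    def _write(seqs: dict[str, str], annotation: list[tuple] | None = None,
               name: str = "mini"):
        counter["n"] += 1
        base = tmp_path / f"g{counter['n']}"
        base.mkdir()
        fasta = base / "genome.fa"
        with open(fasta, "w") as fh:
            for chrom, seq in seqs.items():
                fh.write(f">{chrom}\n{seq}\n")
        ann = None
        if annotation is not None:
            ann = base / "ann.tsv"
            with open(ann, "w") as fh:
                for row in annotation:
                    fh.write("\t".join(str(x) for x in row) + "\n")
        build = encode_genome(fasta, ann, base / "build", name=name)
        return build, fasta, ann

    return _write
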