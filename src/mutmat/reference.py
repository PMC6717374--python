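"""Byte-encoded reference genomes with per-position transcriptional-strand state.

A genome build pre-processes every chromosome of a FASTA reference into a flat
``uint8`` array, one byte per base-pair.  The low three bits store the base
identity (A=0, C=1, G=2, T=3, N=4) and the next two bits store the
transcriptional-strand state of the position derived from the union of gene
footprints in an annotation:

* ``NONTRANSCRIBED`` — covered by no gene footprint,
* ``GENE_ON_REFERENCE_STRAND`` — covered only by genes on the ``+`` strand,
* ``GENE_ON_OPPOSITE_STRAND`` — covered only by genes on the ``-`` strand,
* ``BIDIRECTIONAL`` — covered by genes on both strands.

This makes base identity, flanking sequence context and strand state constant
time queries during matrix generation.  All public coordinates are 1-based
inclusive (the VCF/MAF convention); internal arrays are 0-based.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"
FOOTPRINTS_NAME = "footprints.tsv"
EXONS_NAME = "exons.tsv"


class StrandState(IntEnum):
    NONTRANSCRIBED = 0
    GENE_ON_REFERENCE_STRAND = 1
    GENE_ON_OPPOSITE_STRAND = 2
    BIDIRECTIONAL = 3


_BASES = "ACGTN"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
_STATE_SHIFT = 3
_BASE_MASK = 0b111

# byte -> base translation used to decode whole chromosomes at once
_DECODE_TABLE = np.full(256, ord("N"), dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    for _s in range(4):
        _DECODE_TABLE[_c | (_s << _STATE_SHIFT)] = ord(_b)

# char -> base code; anything outside ACGT (IUPAC ambiguity codes, gaps) encodes as N
_ENCODE_TABLE = np.full(256, _BASE_TO_CODE["N"], dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
    _ENCODE_TABLE[ord(_b.lower())] = _c


def encode_base(base: str, state: StrandState) -> int:
    """Pack one base and one strand state into a single byte."""
    return _BASE_TO_CODE[base] | (int(state) << _STATE_SHIFT)


def decode_base(byte: int) -> tuple[str, StrandState]:
    """Inverse of :func:`encode_base`."""
    return _BASES[byte & _BASE_MASK], StrandState(byte >> _STATE_SHIFT)


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip a leading ``chr``, map ``M`` to ``MT``."""
    name = str(name)
    if name.startswith("chr"):
        name = name[3:]
    if name == "M":
        name = "MT"
    return name


@dataclass
class TranscriptFootprint:
    """Genomic span of one transcript, 1-based inclusive coordinates."""

    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"footprint start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"exon ({s},{e}) outside footprint")


def parse_annotation(path: str | Path) -> list[TranscriptFootprint]:
    """Read a transcript annotation as a list of footprints with exons.

    Two formats are accepted and auto-detected per line count/columns:

    * a refFlat-like TSV with columns ``chrom, strand, txStart, txEnd,
      exonStarts, exonEnds`` where coordinates are 0-based half-open and the
      exon columns are comma-separated lists (possibly empty);
    * GTF, where rows with feature ``transcript`` (or ``gene`` when no
      transcript rows exist) give footprints and ``exon`` rows give exons
      attached to the enclosing footprint by coordinate containment.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        return []
    first = lines[0].split("\t")
    if len(first) >= 8 and first[6] in "+-":
        return _parse_gtf(lines)
    return _parse_tsv(lines)


def _parse_tsv(lines: list[str]) -> list[TranscriptFootprint]:
    out = []
    for ln in lines:
        cols = ln.split("\t")
        if len(cols) < 4:
            logger.warning("skipping malformed annotation line: %r", ln)
            continue
        chrom, strand = normalize_chrom(cols[0]), cols[1]
        tx_start, tx_end = int(cols[2]), int(cols[3])
        exons = []
        if len(cols) >= 6 and cols[4].strip(","):
            starts = [int(x) for x in cols[4].strip(",").split(",")]
            ends = [int(x) for x in cols[5].strip(",").split(",")]
            exons = [(s + 1, e) for s, e in zip(starts, ends)]
        out.append(TranscriptFootprint(chrom, tx_start + 1, tx_end, strand, exons))
    return out


def _parse_gtf(lines: list[str]) -> list[TranscriptFootprint]:
    transcripts, genes, exons = [], [], []
    for ln in lines:
        cols = ln.split("\t")
        if len(cols) < 8:
            logger.warning("skipping malformed GTF line: %r", ln)
            continue
        chrom = normalize_chrom(cols[0])
        feature, strand = cols[2], cols[6]
        start, end = int(cols[3]), int(cols[4])
        row = (chrom, strand, start, end)
        if feature == "transcript":
            transcripts.append(row)
        elif feature == "gene":
            genes.append(row)
        elif feature == "exon":
            exons.append(row)
    rows = transcripts or genes
    if not rows and exons:  # exon-only GTF: footprint per exon
        rows = exons
    out = []
    for chrom, strand, start, end in rows:
        ex = [
            (es, ee)
            for (ec, est, es, ee) in exons
            if ec == chrom and est == strand and start <= es and ee <= end
        ]
        out.append(TranscriptFootprint(chrom, start, end, strand, ex))
    return out


class EncodedChromosome:
    """One chromosome's byte array plus decoded views."""

    def __init__(self, name: str, codes: np.ndarray):
        self.name = name
        self.codes = codes
        self._seq: str | None = None

    def __len__(self) -> int:
        return self.codes.size

    @property
    def seq(self) -> str:
        """Decoded reference-strand sequence (computed once, cached)."""
        if self._seq is None:
            self._seq = _DECODE_TABLE[self.codes].tobytes().decode("ascii")
        return self._seq

    def base(self, position: int) -> str:
        return _BASES[self.codes[position - 1] & _BASE_MASK]

    def state(self, position: int) -> StrandState:
        return StrandState(int(self.codes[position - 1]) >> _STATE_SHIFT)

    def context(self, position: int, flank: int) -> str | None:
        """Reference-strand window of length ``2*flank+1`` centered on
        ``position``; ``None`` when the window runs off a chromosome end."""
        lo, hi = position - flank, position + flank
        if lo < 1 or hi > len(self):
            return None
        return self.seq[lo - 1 : hi]


@dataclass
class GenomeBuild:
    """An installed, byte-encoded reference genome."""

    name: str
    chromosomes: list[tuple[str, int]]
    build_dir: Path
    source_fasta: str = ""
    source_annotation: str = ""

    def __post_init__(self):
        self.build_dir = Path(self.build_dir)
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("non-positive chromosome length")
        self._lengths = dict(self.chromosomes)
        self._cache: tuple[str, EncodedChromosome] | None = None

    @classmethod
    def load(cls, build_dir: str | Path) -> "GenomeBuild":
        build_dir = Path(build_dir)
        manifest = json.loads((build_dir / MANIFEST_NAME).read_text())
        return cls(
            name=manifest["name"],
            chromosomes=[tuple(c) for c in manifest["chromosomes"]],
            build_dir=build_dir,
            source_fasta=manifest.get("source_fasta", ""),
            source_annotation=manifest.get("source_annotation", ""),
        )

    def chromosome_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chromosome_length(self, chrom: str) -> int:
        chrom = normalize_chrom(chrom)
        if chrom not in self._lengths:
            raise KeyError(f"chromosome {chrom!r} not in build {self.name!r}")
        return self._lengths[chrom]

    def load_chromosome(self, chrom: str) -> EncodedChromosome:
        """Load one chromosome's byte array; only the most recent chromosome
        is kept resident (the pipeline's bounded-memory contract)."""
        chrom = normalize_chrom(chrom)
        if self._cache is not None and self._cache[0] == chrom:
            return self._cache[1]
        length = self.chromosome_length(chrom)
        codes = np.fromfile(self.build_dir / f"{chrom}.bin", dtype=np.uint8)
        if codes.size != length:
            raise ValueError(
                f"encoded file for {chrom} has {codes.size} positions, expected {length}"
            )
        ec = EncodedChromosome(chrom, codes)
        self._cache = (chrom, ec)
        return ec

    def context(self, chrom: str, position: int, flank: int) -> str | None:
        """Reference-strand context window, or ``None`` ("context unavailable")
        when the window extends beyond a chromosome end.  Callers must then
        exclude the mutation from context-dependent matrices."""
        ec = self.load_chromosome(chrom)
        if not 1 <= position <= len(ec):
            raise ValueError(f"position {position} outside {chrom} (1..{len(ec)})")
        return ec.context(position, flank)

    def strand_state(self, chrom: str, position: int) -> StrandState:
        ec = self.load_chromosome(chrom)
        if not 1 <= position <= len(ec):
            raise ValueError(f"position {position} outside {chrom} (1..{len(ec)})")
        return ec.state(position)

    def footprints(self) -> list[TranscriptFootprint]:
        path = self.build_dir / FOOTPRINTS_NAME
        out = []
        if not path.exists():
            return out
        for ln in path.read_text().splitlines()[1:]:
            chrom, strand, start, end = ln.split("\t")
            out.append(TranscriptFootprint(chrom, int(start), int(end), strand))
        return out

    def exon_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """1-based inclusive exon intervals per chromosome (exome mode)."""
        path = self.build_dir / EXONS_NAME
        out: dict[str, list[tuple[int, int]]] = {}
        if not path.exists():
            return out
        for ln in path.read_text().splitlines()[1:]:
            chrom, start, end = ln.split("\t")
            out.setdefault(chrom, []).append((int(start), int(end)))
        return out


def encode_genome(
    fasta: str | Path,
    annotation: str | Path | None,
    output_dir: str | Path,
    name: str = "custom",
) -> GenomeBuild:
    """Install a reference genome: encode every chromosome to ``<chrom>.bin``.

    ``annotation`` may be ``None`` (every position NONTRANSCRIBED), a
    refFlat-like TSV, or a GTF.  Annotation chromosomes must resolve against
    FASTA chromosome names after normalization (hard error otherwise);
    footprints extending beyond the chromosome end are rejected with a
    warning.  Same-strand overlapping genes collapse to a footprint union.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    fa = Fasta(str(fasta))
    chrom_map = {normalize_chrom(n): n for n in fa.keys()}

    footprints = parse_annotation(annotation) if annotation is not None else []
    for fp in footprints:
        if fp.chromosome not in chrom_map:
            raise KeyError(
                f"annotation chromosome {fp.chromosome!r} missing from FASTA"
            )

    chromosomes: list[tuple[str, int]] = []
    kept: list[TranscriptFootprint] = []
    for chrom, orig in chrom_map.items():
        seq = str(fa[orig][:]).upper()
        n = len(seq)
        chromosomes.append((chrom, n))
        codes = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
        plus = np.zeros(n, dtype=bool)
        minus = np.zeros(n, dtype=bool)
        for fp in footprints:
            if fp.chromosome != chrom:
                continue
            if fp.end > n or fp.start < 1:
                logger.warning(
                    "rejecting footprint %s:%d-%d beyond chromosome length %d",
                    chrom, fp.start, fp.end, n,
                )
                continue
            kept.append(fp)
            cov = plus if fp.strand == "+" else minus
            cov[fp.start - 1 : fp.end] = True
        state = plus.astype(np.uint8) + 2 * minus.astype(np.uint8)
        codes |= state << _STATE_SHIFT
        codes.tofile(output_dir / f"{chrom}.bin")

    manifest = {
        "name": name,
        "chromosomes": chromosomes,
        "source_fasta": str(fasta),
        "source_annotation": str(annotation) if annotation else "",
    }
    (output_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    with open(output_dir / FOOTPRINTS_NAME, "w") as fh:
        fh.write("chromosome\tstrand\tstart\tend\n")
        for fp in kept:
            fh.write(f"{fp.chromosome}\t{fp.strand}\t{fp.start}\t{fp.end}\n")
    with open(output_dir / EXONS_NAME, "w") as fh:
        fh.write("chromosome\tstart\tend\n")
        for fp in kept:
            for s, e in fp.exons:
                fh.write(f"{fp.chromosome}\t{s}\t{e}\n")
    return GenomeBuild(
        name=name,
        chromosomes=chromosomes,
        build_dir=output_dir,
        source_fasta=str(fasta),
        source_annotation=str(annotation) if annotation else "",
    )
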