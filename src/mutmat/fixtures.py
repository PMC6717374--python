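"""Synthetic genomes, annotations and mutation catalogues with known truth.

``make_genome`` writes a small multi-chromosome FASTA whose sequence contains
engineered loci with known ground truth — homopolymer runs, tandem repeat
tracts and microhomology cassettes, each insulated by guard bases so the
constructed repeat/overlap counts are exact — plus an annotation placing
forward-strand, reverse-strand, overlapping (bidirectional) and intergenic
regions.  ``make_catalogue`` emits per-sample VCFs drawing substitutions,
doublets, indels at the engineered loci and complex events, together with a
truth table of expected finest-resolution channels.

``NaiveOracle`` classifies one mutation at a time by direct string operations
on the FASTA and interval scans over the raw annotation — no byte encoding,
no caching — and serves as the independent cross-check for the optimized
pipeline.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

from .reference import TranscriptFootprint, parse_annotation
from .util import ClassificationError
from .variant_io import COMPLEX, DBS, ID_DEL, ID_INS, SBS, MutationRecord

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# fixture specification


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Per-sample event counts default to a small catalogue that exercises every
    event family; fractions are in [0, 1] and all randomness flows from
    ``seed``.
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (20000, 15000, 12000)
    chromosome_names: tuple[str, ...] | None = None
    gene_density: float = 0.4
    bidirectional_fraction: float = 0.1
    n_samples: int = 4
    n_sbs: int = 40
    n_adjacent_pairs: int = 4
    n_dbs: int = 10
    n_homopolymer_indels: int = 10
    n_repeat_indels: int = 10
    n_mh_deletions: int = 6
    n_complex: int = 2
    right_aligned_fraction: float = 0.3

    def __post_init__(self):
        for frac in (self.gene_density, self.bidirectional_fraction,
                     self.right_aligned_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.chromosome_names is None:
            self.chromosome_names = tuple(
                str(i + 1) for i in range(len(self.chromosome_lengths))
            )
        if len(self.chromosome_names) != len(self.chromosome_lengths):
            raise ValueError("chromosome_names and chromosome_lengths differ in length")

    @classmethod
    def human_layout(cls, seed: int = 0, length: int = 5000, **kwargs) -> "FixtureSpec":
        """A genome with the human chromosome naming layout (1-22, X, Y, MT)."""
        names = tuple([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])
        return cls(
            seed=seed,
            chromosome_names=names,
            chromosome_lengths=tuple([length] * 25),
            **kwargs,
        )


# ---------------------------------------------------------------------------
# genome construction


def _pick_other(rng, exclude: set[str]) -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[rng.integers(len(choices))]


def _primitive_unit(rng, length: int) -> str:
    """A repeat unit that is not itself periodic (so copy counts are exact)."""
    while True:
        unit = "".join(rng.choice(list(_BASES), size=length))
        if len(set(unit)) < 2:
            continue
        if any(
            length % k == 0 and unit == unit[:k] * (length // k)
            for k in range(1, length)
        ):
            continue
        return unit


def _implant_loci(rng, seq: list[str], chrom: str, length: int) -> list[dict]:
    """Overwrite engineered loci into a background sequence; each locus is
    flanked by guard bases chosen to break any accidental tiling or overlap."""
    loci = []
    cursor = 150
    def room(span):
        return cursor + span + 2 < length - 150

    for _ in range(2):  # homopolymers
        run = int(rng.integers(4, 9))
        base = _BASES[rng.integers(4)]
        if not room(run):
            break
        g5 = _pick_other(rng, {base})
        g3 = _pick_other(rng, {base})
        seq[cursor - 1] = g5
        seq[cursor : cursor + run] = [base] * run
        seq[cursor + run] = g3
        loci.append({
            "chromosome": chrom, "kind": "homopolymer",
            "start": cursor + 1, "end": cursor + run, "base": base, "run": run,
        })
        cursor += run + int(rng.integers(40, 81))

    for _ in range(2):  # tandem repeats
        unit = _primitive_unit(rng, int(rng.integers(2, 5)))
        copies = int(rng.integers(2, 5))
        span = len(unit) * copies
        if not room(span):
            break
        g5 = _pick_other(rng, {unit[-1]})
        g3 = _pick_other(rng, {unit[0]})
        seq[cursor - 1] = g5
        seq[cursor : cursor + span] = list(unit * copies)
        seq[cursor + span] = g3
        loci.append({
            "chromosome": chrom, "kind": "repeat",
            "start": cursor + 1, "end": cursor + span,
            "unit": unit, "copies": copies,
        })
        cursor += span + int(rng.integers(40, 81))

    for _ in range(2):  # microhomology cassettes: [motif][motif prefix]
        mlen = int(rng.integers(3, 6))
        motif = _primitive_unit(rng, mlen)
        mh = int(rng.integers(1, mlen))
        span = mlen + mh
        if not room(span):
            break
        g5 = _pick_other(rng, {motif[-1]})
        g3 = _pick_other(rng, {motif[mh]} if mh < mlen else set())
        seq[cursor - 1] = g5
        seq[cursor : cursor + span] = list(motif + motif[:mh])
        seq[cursor + span] = g3
        loci.append({
            "chromosome": chrom, "kind": "mh",
            "start": cursor + 1, "end": cursor + mlen,
            "motif": motif, "mh": mh,
        })
        cursor += span + int(rng.integers(40, 81))
    return loci


def _gene_layout(spec: FixtureSpec, length: int) -> list[TranscriptFootprint]:
    """Forward, reverse and (optionally) overlapping gene footprints with two
    exons each; footprint extents scale with ``gene_density``."""
    g = spec.gene_density
    out = []

    def gene(chrom_frac_start, frac_len, strand):
        start = max(2, int(length * chrom_frac_start))
        end = min(length - 1, start + max(20, int(length * frac_len)))
        third = (end - start) // 3
        exons = [(start, start + third), (end - third, end)]
        return TranscriptFootprint("?", start, end, strand, exons)

    out.append(gene(0.05, 0.35 * g, "+"))
    out.append(gene(0.45, 0.30 * g, "-"))
    if spec.bidirectional_fraction > 0:
        flen = max(0.02, 0.15 * g)
        a = gene(0.70, flen, "+")
        b_start_frac = 0.70 + flen * (1 - spec.bidirectional_fraction)
        b = gene(b_start_frac, flen, "-")
        out += [a, b]
    return out


def make_genome(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write ``genome.fa``, ``annotation.tsv`` and ``manifest.json``.

    Deterministic for a fixed spec; the manifest records every engineered
    locus's ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    loci_all = []
    fasta_path = out_dir / "genome.fa"
    ann_path = out_dir / "annotation.tsv"
    with open(fasta_path, "w") as fa, open(ann_path, "w") as ann:
        for chrom, length in zip(spec.chromosome_names, spec.chromosome_lengths):
            if length < 600:
                raise ValueError(f"chromosome length {length} too small for loci")
            seq = list(rng.choice(list(_BASES), size=length))
            loci_all += _implant_loci(rng, seq, chrom, length)
            fa.write(f">{chrom}\n")
            text = "".join(seq)
            for i in range(0, length, 60):
                fa.write(text[i : i + 60] + "\n")
            for fp in _gene_layout(spec, length):
                starts = ",".join(str(s - 1) for s, _ in fp.exons)
                ends = ",".join(str(e) for _, e in fp.exons)
                ann.write(
                    f"{chrom}\t{fp.strand}\t{fp.start - 1}\t{fp.end}\t{starts}\t{ends}\n"
                )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"loci": loci_all}, indent=1))
    return {"fasta": fasta_path, "annotation": ann_path, "manifest": manifest_path}


# ---------------------------------------------------------------------------
# naive oracle


def _rc(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


class NaiveOracle:
    """Per-mutation classifier working directly on FASTA text and raw
    annotation intervals; intentionally simple and slow."""

    def __init__(self, fasta: str | Path, annotation: str | Path | None):
        self.fa = Fasta(str(fasta))
        self.footprints = list(parse_annotation(annotation)) if annotation else []

    def seq(self, chrom: str) -> str:
        return str(self.fa[chrom][:]).upper()

    def state_label(self, chrom: str, position: int) -> str:
        """'none', 'plus', 'minus' or 'both' coverage by gene footprints."""
        plus = minus = False
        for fp in self.footprints:
            if fp.chromosome == chrom and fp.start <= position <= fp.end:
                if fp.strand == "+":
                    plus = True
                else:
                    minus = True
        if plus and minus:
            return "both"
        if plus:
            return "plus"
        if minus:
            return "minus"
        return "none"

    def _tub(self, chrom: str, position: int, pyr_on_reference: bool) -> str:
        cov = self.state_label(chrom, position)
        if cov == "none":
            return "N"
        if cov == "both":
            return "B"
        coding_is_reference = cov == "plus"
        if coding_is_reference:
            return "U" if pyr_on_reference else "T"
        return "T" if pyr_on_reference else "U"

    def classify(self, record: MutationRecord) -> tuple[str, str]:
        """(finest scheme, channel label), mirroring the pipeline's labels."""
        if record.event_class == SBS:
            return self._classify_sbs(record)
        if record.event_class == DBS:
            return self._classify_dbs(record)
        if record.event_class in (ID_INS, ID_DEL):
            return self._classify_indel(record)
        return (COMPLEX, "")

    def _classify_sbs(self, rec: MutationRecord) -> tuple[str, str]:
        seq = self.seq(rec.chromosome)
        if seq[rec.position - 1] != rec.ref:
            raise ClassificationError("ref_mismatch")
        if rec.ref == "N" or rec.alt == "N":
            raise ClassificationError("n_allele")
        lo, hi = rec.position - 3, rec.position + 2
        window = seq[max(lo, 0) : hi] if lo >= 0 and hi <= len(seq) else None
        ref, alt = rec.ref, rec.alt
        if window is not None and "N" not in window:
            if ref in "AG":
                window, ref, alt = _rc(window), _rc(ref), _rc(alt)
                pyr_on_ref = False
            else:
                pyr_on_ref = True
            tub = self._tub(rec.chromosome, rec.position, pyr_on_ref)
            return "SBS6144", f"{tub}:{window[:2]}[{ref}>{alt}]{window[3:]}"
        pyr_on_ref = ref in "CT"
        if not pyr_on_ref:
            ref, alt = _rc(ref), _rc(alt)
        tub = self._tub(rec.chromosome, rec.position, pyr_on_ref)
        return "SBS24", f"{tub}:{ref}>{alt}"

    @staticmethod
    def _canonical_doublet(ref2: str, alt2: str) -> tuple[str, str, bool]:
        rr, ra = _rc(ref2), _rc(alt2)
        score = sum(c in "CT" for c in ref2 + alt2)
        score_rc = sum(c in "CT" for c in rr + ra)
        if score > score_rc or (score == score_rc and (ref2, alt2) <= (rr, ra)):
            return ref2, alt2, False
        return rr, ra, True

    def _classify_dbs(self, rec: MutationRecord) -> tuple[str, str]:
        seq = self.seq(rec.chromosome)
        if seq[rec.position - 1 : rec.position + 1] != rec.ref:
            raise ClassificationError("ref_mismatch")
        if "N" in rec.ref + rec.alt:
            raise ClassificationError("n_allele")
        cref, calt, flipped = self._canonical_doublet(rec.ref, rec.alt)
        cov = self.state_label(rec.chromosome, rec.position)
        pure = set(cref) <= set("CT") or set(cref) <= set("AG")
        if cov == "none":
            label = "N"
        elif not pure:
            label = "Q"
        elif cov == "both":
            label = "B"
        else:
            pyr_on_ref = (set(cref) <= set("CT")) ^ flipped
            coding_is_reference = cov == "plus"
            if coding_is_reference:
                label = "U" if pyr_on_ref else "T"
            else:
                label = "T" if pyr_on_ref else "U"
        five = seq[rec.position - 2] if rec.position >= 2 else None
        three = seq[rec.position + 1] if rec.position + 1 < len(seq) else None
        if five is None or three is None or "N" in five + three:
            return "DBS186", f"{label}:{cref}>{calt}"
        if flipped:
            five, three = _rc(three), _rc(five)
        return "DBS2976", f"{label}:{five}{cref}{three}>{five}{calt}{three}"

    def _classify_indel(self, rec: MutationRecord) -> tuple[str, str]:
        seq = self.seq(rec.chromosome)
        deletion = rec.event_class == ID_DEL
        motif = rec.ref if deletion else rec.alt
        if set(motif) - set("ACGT"):
            raise ClassificationError("n_allele")
        if deletion:
            start = rec.position - 1
            if seq[start : start + len(motif)] != motif:
                raise ClassificationError("ref_mismatch")
        else:
            start = rec.position  # 0-based insertion point
        # left-align by single shifts
        while start > 0 and seq[start - 1] == motif[-1]:
            start -= 1
            motif = seq[start] + motif[:-1]
        L = len(motif)
        after = start + L if deletion else start
        copies = 1 if deletion else 0
        k = after
        while seq[k : k + L] == motif:
            copies += 1
            k += L
        k = start - L
        while k >= 0 and seq[k : k + L] == motif:
            copies += 1
            k -= L
        kind = "Del" if deletion else "Ins"
        lc = str(L) if L < 5 else "5+"

        def cap(n, c):
            return str(n) if n < c else f"{c}+"

        size_cap = 6 if deletion else 5
        if L == 1:
            sub = "C" if motif in "CG" else "T"
            core = f"1:{kind}:{sub}:{cap(copies, size_cap)}"
        elif deletion and copies == 1:
            mh3 = 0
            while mh3 + 1 < L and after + mh3 < len(seq) and seq[after + mh3] == motif[mh3]:
                mh3 += 1
            mh5 = 0
            while mh5 + 1 < L and start - mh5 - 1 >= 0 and seq[start - mh5 - 1] == motif[L - mh5 - 1]:
                mh5 += 1
            mh = max(mh3, mh5)
            core = f"{lc}:Del:M:{cap(mh, 5)}" if mh else f"{lc}:Del:R:1"
        else:
            core = f"{lc}:{kind}:R:{cap(copies, size_cap)}"

        site = start + 1 if deletion else min(start + 1, len(seq))
        cov = self.state_label(rec.chromosome, max(site, 1))
        pure_pyr = set(motif) <= set("CT")
        pure_pur = set(motif) <= set("AG")
        if cov == "none":
            label = "N"
        elif not (pure_pyr or pure_pur):
            label = "Q"
        elif cov == "both":
            label = "B"
        else:
            coding_is_reference = cov == "plus"
            if coding_is_reference:
                label = "U" if pure_pyr else "T"
            else:
                label = "T" if pure_pyr else "U"
        return "ID415", f"{label}:{core}"


# ---------------------------------------------------------------------------
# catalogue construction


@dataclass
class _TruthRow:
    sample: str
    chromosome: str
    position: int
    ref: str
    alt: str
    event_class: str
    level: str
    expected_channel: str
    expected_core: str = ""
    locus_kind: str = ""


def _vcf_indel_fields(seq: str, kind: str, position: int, motif: str):
    """Internal indel representation -> anchored VCF (pos, ref, alt)."""
    if kind == ID_DEL:
        anchor = seq[position - 2]
        return position - 1, anchor + motif, anchor
    anchor = seq[position - 1]
    return position, anchor, anchor + motif


def make_catalogue(
    spec: FixtureSpec, genome_dir: str | Path, out_dir: str | Path
) -> dict[str, object]:
    """Emit one VCF per synthetic sample plus ``truth.tsv`` of expected
    finest-resolution channels (computed independently of the pipeline, by
    construction at engineered loci and by the naive oracle elsewhere)."""
    genome_dir, out_dir = Path(genome_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    oracle = NaiveOracle(genome_dir / "genome.fa", genome_dir / "annotation.tsv")
    manifest = json.loads((genome_dir / "manifest.json").read_text())
    loci = manifest["loci"]
    chroms = list(spec.chromosome_names)
    seqs = {c: oracle.seq(c) for c in chroms}

    def cap(n, c):
        return str(n) if n < c else f"{c}+"

    vcf_paths = []
    truth: list[_TruthRow] = []
    for si in range(spec.n_samples):
        sample = f"S{si + 1}"
        used: dict[str, set[int]] = {c: set() for c in chroms}

        def reserve(chrom, lo, hi, margin=3):
            for p in range(lo - margin, hi + margin + 1):
                used[chrom].add(p)

        def free(chrom, lo, hi):
            return all(p not in used[chrom] for p in range(lo - 3, hi + 4))

        def pick_position(chrom, width=1):
            L = len(seqs[chrom])
            for _ in range(200):
                p = int(rng.integers(4, L - width - 3))
                if free(chrom, p, p + width - 1):
                    return p
            raise RuntimeError("could not place event; chromosome too crowded")

        # keep random substitutions clear of the engineered indel loci
        for locus in loci:
            reserve(locus["chromosome"], locus["start"],
                    locus["end"] + locus.get("mh", 0))

        rows: list[tuple[str, int, str, str]] = []  # (chrom, vcf_pos, ref, alt)
        emitted: set[tuple[str, int, str, str]] = set()

        def emit(chrom, vpos, vref, valt) -> bool:
            key = (chrom, vpos, vref, valt)
            if key in emitted:
                return False
            emitted.add(key)
            rows.append(key)
            return True

        def add_truth(rec: MutationRecord, core="", locus=""):
            level, channel = oracle.classify(rec)
            truth.append(_TruthRow(
                sample, rec.chromosome, rec.position, rec.ref, rec.alt,
                rec.event_class, level, channel, core, locus,
            ))

        # --- substitutions, round-robin over chromosomes
        for i in range(spec.n_sbs):
            chrom = chroms[i % len(chroms)]
            p = pick_position(chrom)
            ref = seqs[chrom][p - 1]
            alt = _pick_other(rng, {ref})
            reserve(chrom, p, p)
            emit(chrom, p, ref, alt)
            add_truth(MutationRecord(sample, chrom, p, ref, alt, SBS))

        # --- adjacent SBS pairs (merged downstream into doublets)
        for i in range(spec.n_adjacent_pairs):
            chrom = chroms[i % len(chroms)]
            p = pick_position(chrom, width=2)
            r1, r2 = seqs[chrom][p - 1], seqs[chrom][p]
            a1, a2 = _pick_other(rng, {r1}), _pick_other(rng, {r2})
            reserve(chrom, p, p + 1)
            emit(chrom, p, r1, a1)
            emit(chrom, p + 1, r2, a2)
            add_truth(MutationRecord(sample, chrom, p, r1 + r2, a1 + a2, DBS))

        # --- direct doublets
        for i in range(spec.n_dbs):
            chrom = chroms[i % len(chroms)]
            p = pick_position(chrom, width=2)
            ref2 = seqs[chrom][p - 1 : p + 1]
            alt2 = _pick_other(rng, {ref2[0]}) + _pick_other(rng, {ref2[1]})
            reserve(chrom, p, p + 1)
            emit(chrom, p, ref2, alt2)
            add_truth(MutationRecord(sample, chrom, p, ref2, alt2, DBS))

        # --- indels at engineered loci (loci may host several distinct events)
        hp = [l for l in loci if l["kind"] == "homopolymer"]
        rp = [l for l in loci if l["kind"] == "repeat"]
        mh = [l for l in loci if l["kind"] == "mh"]

        for i in range(spec.n_homopolymer_indels if hp else 0):
            locus = hp[int(rng.integers(len(hp)))]
            chrom, base, run = locus["chromosome"], locus["base"], locus["run"]
            sub = "C" if base in "CG" else "T"
            if i % 2 == 0:  # delete one base
                pos = locus["start"]
                if rng.random() < spec.right_aligned_fraction:
                    pos = locus["end"]  # right-aligned caller representation
                vpos, vref, valt = _vcf_indel_fields(seqs[chrom], ID_DEL, pos, base)
                if emit(chrom, vpos, vref, valt):
                    add_truth(
                        MutationRecord(sample, chrom, pos, base, "", ID_DEL),
                        f"1:Del:{sub}:{cap(run, 6)}", "homopolymer",
                    )
            else:  # insert one more base
                pos = locus["start"] + int(rng.integers(run))
                vpos, vref, valt = _vcf_indel_fields(seqs[chrom], ID_INS, pos, base)
                if emit(chrom, vpos, vref, valt):
                    add_truth(
                        MutationRecord(sample, chrom, pos, "", base, ID_INS),
                        f"1:Ins:{sub}:{cap(run, 5)}", "homopolymer",
                    )

        for i in range(spec.n_repeat_indels if rp else 0):
            locus = rp[int(rng.integers(len(rp)))]
            chrom, unit, copies = locus["chromosome"], locus["unit"], locus["copies"]
            ulen = len(unit)
            lc = str(ulen) if ulen < 5 else "5+"
            if i % 2 == 0:  # delete one unit, at a random copy offset
                offset = int(rng.integers(copies))
                pos = locus["start"] + offset * ulen
                vpos, vref, valt = _vcf_indel_fields(seqs[chrom], ID_DEL, pos, unit)
                if emit(chrom, vpos, vref, valt):
                    add_truth(
                        MutationRecord(sample, chrom, pos, unit, "", ID_DEL),
                        f"{lc}:Del:R:{cap(copies, 6)}", "repeat",
                    )
            else:  # insert one more unit at a random copy boundary
                pos = locus["start"] - 1 + int(rng.integers(copies + 1)) * ulen
                vpos, vref, valt = _vcf_indel_fields(seqs[chrom], ID_INS, pos, unit)
                if emit(chrom, vpos, vref, valt):
                    add_truth(
                        MutationRecord(sample, chrom, pos, "", unit, ID_INS),
                        f"{lc}:Ins:R:{cap(copies, 5)}", "repeat",
                    )

        for i in range(spec.n_mh_deletions if mh else 0):
            locus = mh[int(rng.integers(len(mh)))]
            chrom, motif, mhlen = locus["chromosome"], locus["motif"], locus["mh"]
            pos, dmotif = locus["start"], motif
            if rng.random() < spec.right_aligned_fraction:
                # equivalent representation shifted into the homologous tail
                pos = locus["start"] + mhlen
                dmotif = motif[mhlen:] + motif[:mhlen]
            vpos, vref, valt = _vcf_indel_fields(seqs[chrom], ID_DEL, pos, dmotif)
            lc = str(len(motif)) if len(motif) < 5 else "5+"
            if emit(chrom, vpos, vref, valt):
                add_truth(
                    MutationRecord(sample, chrom, pos, dmotif, "", ID_DEL),
                    f"{lc}:Del:M:{cap(mhlen, 5)}", "mh",
                )

        # --- complex events (deletion plus insertion at one locus)
        for i in range(spec.n_complex):
            chrom = chroms[i % len(chroms)]
            p = pick_position(chrom, width=2)
            ref2 = seqs[chrom][p - 1 : p + 1]
            alt3 = (
                _pick_other(rng, {ref2[0]})
                + _BASES[rng.integers(4)]
                + _pick_other(rng, {ref2[1]})
            )
            reserve(chrom, p, p + 1)
            emit(chrom, p, ref2, alt3)
            truth.append(_TruthRow(
                sample, chrom, p, ref2, alt3, COMPLEX, COMPLEX, "", "", "",
            ))

        path = out_dir / f"{sample}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c},length={len(seqs[c])}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            order = {c: i for i, c in enumerate(chroms)}
            for chrom, pos, ref, alt in sorted(rows, key=lambda r: (order[r[0]], r[1])):
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")
        vcf_paths.append(path)

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "sample\tchromosome\tposition\tref\talt\tevent_class\t"
            "level\texpected_channel\texpected_core\tlocus_kind\n"
        )
        for t in truth:
            fh.write(
                f"{t.sample}\t{t.chromosome}\t{t.position}\t{t.ref or '-'}\t"
                f"{t.alt or '-'}\t{t.event_class}\t{t.level}\t{t.expected_channel}\t"
                f"{t.expected_core}\t{t.locus_kind}\n"
            )
    return {"vcfs": vcf_paths, "truth": truth_path}


def random_events(
    spec: FixtureSpec,
    genome_dir: str | Path,
    n_events: int,
    seed: int | None = None,
) -> list[MutationRecord]:
    """Random well-formed events of all classes at arbitrary positions,
    for oracle-equivalence testing (no ground truth needed)."""
    genome_dir = Path(genome_dir)
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    fa = Fasta(str(genome_dir / "genome.fa"))
    seqs = {c: str(fa[c][:]).upper() for c in spec.chromosome_names}
    chroms = list(spec.chromosome_names)
    out = []
    for i in range(n_events):
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = seqs[chrom]
        kind = rng.random()
        p = int(rng.integers(1, len(seq) + 1))
        if kind < 0.4:  # SBS anywhere, including chromosome edges
            ref = seq[p - 1]
            out.append(MutationRecord("R", chrom, p, ref, _pick_other(rng, {ref}), SBS))
        elif kind < 0.6:  # DBS
            p = min(p, len(seq) - 1)
            ref2 = seq[p - 1 : p + 1]
            alt2 = _pick_other(rng, {ref2[0]}) + _pick_other(rng, {ref2[1]})
            out.append(MutationRecord("R", chrom, p, ref2, alt2, DBS))
        elif kind < 0.8:  # deletion of 1-6 reference bases
            L = int(rng.integers(1, 7))
            p = min(p, len(seq) - L + 1)
            out.append(MutationRecord("R", chrom, p, seq[p - 1 : p - 1 + L], "", ID_DEL))
        else:  # insertion of a random motif
            L = int(rng.integers(1, 7))
            motif = "".join(rng.choice(list(_BASES), size=L))
            out.append(MutationRecord("R", chrom, p, "", motif, ID_INS))
    return out
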