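"""Single base substitution channels.

An SBS is reported by the pyrimidine member of the mutated Watson-Crick pair:
a mutation whose reference base is a purine is reverse-complemented together
with its flanking context.  With the immediate 5'/3' bases this yields the
96-channel trinucleotide classification, with two bases each side the
1536-channel pentanucleotide one, and with the transcriptional strand label
(T/U/B/N) prefixed, SBS-384 and SBS-6144.

Channel label grammar: ``"AC[C>A]GT"`` (pentanucleotide core) and
``"T:AC[C>A]GT"`` (strand-labeled).  The mutated pyrimidine and its
alternative sit inside the brackets; flanks read 5'→3' on the pyrimidine
strand.
"""
from __future__ import annotations

import re
from itertools import product

from .reference import StrandState
from .util import (
    PYRIMIDINES,
    RefMismatchError,
    UnclassifiableError,
    revcomp,
)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
STRAND_LABELS = ("T", "U", "B", "N")

_CORE_RE = re.compile(r"^(?:([TUBNQ]):)?([ACGT]*)\[([CT])>([ACGT])\]([ACGT]*)$")


def parse_core(label: str) -> tuple[str | None, str, str, str, str]:
    """Split a channel label into (strand, 5' flank, ref, alt, 3' flank)."""
    m = _CORE_RE.match(label)
    if not m:
        # flankless labels: "C>A" or "N:C>A"
        strand = None
        core = label
        if ":" in label:
            strand, core = label.split(":", 1)
        ref, alt = core.split(">")
        return strand, "", ref, alt, ""
    return m.group(1), m.group(2), m.group(3), m.group(4), m.group(5)


def render_core(five: str, ref: str, alt: str, three: str) -> str:
    if not five and not three:
        return f"{ref}>{alt}"
    return f"{five}[{ref}>{alt}]{three}"


def orient_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, bool]:
    """Return the pyrimidine-oriented core label and whether the event was
    reverse-complemented to get there.

    ``context`` is the reference-strand window centered on the mutated base
    (odd length, center == ``ref``).
    """
    if ref == "N" or alt == "N":
        raise UnclassifiableError("n_allele")
    flank = len(context) // 2
    if context[flank] != ref:
        raise ValueError(f"context center {context[flank]!r} != ref {ref!r}")
    flipped = False
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = revcomp(ref)
        alt = revcomp(alt)
        flipped = True
    return render_core(context[:flank], ref, alt, context[flank + 1 :]), flipped


def sbs_strand_label(state: StrandState, was_reverse_complemented: bool) -> str:
    """Transcriptional strand label for a pyrimidine-oriented substitution.

    When the gene lies on the reference strand the reference strand is the
    coding (untranscribed) strand, so a pyrimidine already on the reference
    strand is untranscribed (U) and a flipped one transcribed (T); a gene on
    the opposite strand swaps the two.
    """
    if state == StrandState.NONTRANSCRIBED:
        return "N"
    if state == StrandState.BIDIRECTIONAL:
        return "B"
    if state == StrandState.GENE_ON_REFERENCE_STRAND:
        return "T" if was_reverse_complemented else "U"
    return "U" if was_reverse_complemented else "T"


def classify_sbs(
    seq: str, state: StrandState, position: int, ref: str, alt: str
) -> tuple[str, str]:
    """Classify one SBS at its finest available resolution.

    Returns ``("SBS6144", label)`` when the full ±2 bp pentanucleotide window
    is on-chromosome and N-free, else ``("SBS24", label)``: events lacking
    usable context are still counted in the context-free strand classification
    (collapsing further to SBS-6) but excluded from 96/384/1536/6144.
    """
    if seq[position - 1] != ref:
        raise RefMismatchError(f"reference is {seq[position - 1]!r}, record says {ref!r}")
    if ref == "N" or alt == "N":
        raise UnclassifiableError("n_allele")
    penta = None
    if 2 < position <= len(seq) - 2:
        penta = seq[position - 3 : position + 2]
    if penta is not None and "N" not in penta:
        core, flipped = orient_pyrimidine(ref, alt, penta)
        return "SBS6144", f"{sbs_strand_label(state, flipped)}:{core}"
    core, flipped = orient_pyrimidine(ref, alt, ref)
    return "SBS24", f"{sbs_strand_label(state, flipped)}:{core}"


def enumerate_cores(flank: int) -> list[str]:
    """All pyrimidine-oriented substitution cores with ``flank`` bases each
    side: 6, 96 or 1536 channels for flank 0, 1, 2."""
    out = []
    for sub in SUBSTITUTIONS:
        ref, alt = sub.split(">")
        for five in product("ACGT", repeat=flank):
            for three in product("ACGT", repeat=flank):
                out.append(render_core("".join(five), ref, alt, "".join(three)))
    return out


def enumerate_channels(scheme: str) -> list[str]:
    flanks = {"SBS6": 0, "SBS96": 1, "SBS1536": 2}
    stranded = {"SBS24": 0, "SBS384": 1, "SBS6144": 2}
    if scheme in flanks:
        return enumerate_cores(flanks[scheme])
    if scheme in stranded:
        return [
            f"{s}:{core}"
            for core in enumerate_cores(stranded[scheme])
            for s in STRAND_LABELS
        ]
    raise KeyError(f"unknown SBS scheme {scheme!r}")


# ---- collapse label maps -------------------------------------------------

def strip_strand(label: str) -> str:
    return label.split(":", 1)[1]


def trim_flanks(label: str) -> str:
    """Drop the outermost flanking base on each side (penta→tri, tri→core),
    preserving a strand prefix when present."""
    strand, five, ref, alt, three = parse_core(label)
    core = render_core(five[1:] if five else "", ref, alt, three[:-1] if three else "")
    return f"{strand}:{core}" if strand else core
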