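"""Doublet base substitution channels.

A DBS replaces two adjacent base-pairs at once.  Each event has two
equivalent renderings (reference strand and its reverse complement); the
canonical one is the rendering with the larger total number of pyrimidines
across ref and alt doublets, with ties broken deterministically
(lexicographically smaller ref doublet, then alt).  Grouping all 16×9 ordered
doublet substitutions by reverse-complement equivalence yields 78 canonical
classes (DBS-78).  Adding one flanking base each side gives the
tetranucleotide-context classification (16 contexts per class, DBS-1248), and
transcriptional strand labels give DBS-186 and the strand-labeled context
matrix (DBS-2976).

Strand orientability: only doublets whose reference doublet is a pure
pyrimidine or pure purine stretch can be attributed to a strand; mixed
doublets in transcribed regions are labeled Q (unknown).

Label grammar: ``"CC>TT"`` (class), ``"ACCA>ATTA"`` (context),
``"T:CC>TT"`` / ``"T:ACCA>ATTA"`` (strand-labeled).
"""
from __future__ import annotations

from itertools import product

from .reference import StrandState
from .sbs import sbs_strand_label
from .util import (
    RefMismatchError,
    UnclassifiableError,
    is_pure_purine,
    is_pure_pyrimidine,
    revcomp,
)


def _n_pyrimidines(seq: str) -> int:
    return sum(c in "CT" for c in seq)


def _build_canonical_table() -> dict[tuple[str, str], tuple[str, str]]:
    table = {}
    for ref in ("".join(p) for p in product("ACGT", repeat=2)):
        for alt in ("".join(p) for p in product("ACGT", repeat=2)):
            if alt[0] == ref[0] or alt[1] == ref[1]:
                continue
            pair = (ref, alt)
            flipped = (revcomp(ref), revcomp(alt))
            score = _n_pyrimidines(ref) + _n_pyrimidines(alt)
            score_f = _n_pyrimidines(flipped[0]) + _n_pyrimidines(flipped[1])
            if score > score_f:
                canon = pair
            elif score_f > score:
                canon = flipped
            else:
                canon = min(pair, flipped)
            table[pair] = canon
    return table


#: every ordered doublet substitution -> its canonical representative
CANONICAL_TABLE = _build_canonical_table()
#: the 78 canonical classes, sorted (grouped by reference doublet)
CANONICAL_CLASSES = sorted(set(CANONICAL_TABLE.values()))


def canonical_dbs(ref2: str, alt2: str) -> tuple[tuple[str, str], bool]:
    """Canonicalize a doublet substitution.

    Returns the canonical (ref, alt) pair and whether the input had to be
    reverse-complemented.  Palindromic classes map to themselves unflipped.
    """
    if "N" in ref2 + alt2:
        raise UnclassifiableError("n_allele")
    key = (ref2, alt2)
    if key not in CANONICAL_TABLE:
        raise UnclassifiableError(
            "not_dbs", f"{ref2}>{alt2} does not differ at both positions"
        )
    canon = CANONICAL_TABLE[key]
    return canon, canon != key


def is_orientable(ref2: str) -> bool:
    """True when one strand of the reference doublet is a pure pyrimidine
    stretch (equivalently the other is pure purine)."""
    return is_pure_pyrimidine(ref2) or is_pure_purine(ref2)


def dbs_strand_label(state: StrandState, canonical_ref: str, was_flipped: bool) -> str:
    """Strand label for a canonicalized doublet.

    Outside transcribed regions every doublet is N.  Inside, unorientable
    doublets are Q; orientable ones are labeled like substitutions, orienting
    on the physical strand carrying the pyrimidine stretch (when the canonical
    notation reads the purine strand the flip flag is inverted).
    """
    if state == StrandState.NONTRANSCRIBED:
        return "N"
    if not is_orientable(canonical_ref):
        return "Q"
    if state == StrandState.BIDIRECTIONAL:
        return "B"
    effective_flip = was_flipped ^ is_pure_purine(canonical_ref)
    return sbs_strand_label(state, effective_flip)


def strand_labels_for(canonical_ref: str) -> tuple[str, ...]:
    """The reachable strand labels of a canonical class under the rules
    above (used to derive the DBS-186 / DBS-2976 channel sets)."""
    if is_orientable(canonical_ref):
        return ("T", "U", "B", "N")
    return ("N", "Q")


def classify_dbs(
    seq: str, state: StrandState, position: int, ref2: str, alt2: str
) -> tuple[str, str]:
    """Classify one DBS at its finest available resolution.

    ``position`` is the 1-based position of the 5' base of the doublet; the
    strand state is taken at that base.  Returns ``("DBS2976", label)`` when
    both flanking bases are on-chromosome and N-free, else ``("DBS186",
    label)`` (such events still collapse into DBS-78/186 but are excluded
    from the context matrices).
    """
    observed = seq[position - 1 : position + 1]
    if observed != ref2:
        raise RefMismatchError(f"reference is {observed!r}, record says {ref2!r}")
    (cref, calt), flipped = canonical_dbs(ref2, alt2)
    label = dbs_strand_label(state, cref, flipped)
    five = seq[position - 2] if position >= 2 else None
    three = seq[position + 1] if position + 1 < len(seq) else None
    if five is not None and three is not None and "N" not in five + three:
        if flipped:
            five, three = revcomp(three), revcomp(five)
        return "DBS2976", f"{label}:{five}{cref}{three}>{five}{calt}{three}"
    return "DBS186", f"{label}:{cref}>{calt}"


def enumerate_channels(scheme: str) -> list[str]:
    if scheme == "DBS78":
        return [f"{r}>{a}" for r, a in CANONICAL_CLASSES]
    if scheme == "DBS1248":
        return [
            f"{f}{r}{t}>{f}{a}{t}"
            for r, a in CANONICAL_CLASSES
            for f in "ACGT"
            for t in "ACGT"
        ]
    if scheme == "DBS186":
        return [
            f"{s}:{r}>{a}"
            for r, a in CANONICAL_CLASSES
            for s in strand_labels_for(r)
        ]
    if scheme == "DBS2976":
        return [
            f"{s}:{f}{r}{t}>{f}{a}{t}"
            for r, a in CANONICAL_CLASSES
            for f in "ACGT"
            for t in "ACGT"
            for s in strand_labels_for(r)
        ]
    raise KeyError(f"unknown DBS scheme {scheme!r}")


# ---- collapse label maps -------------------------------------------------

def strip_strand(label: str) -> str:
    return label.split(":", 1)[1]


def trim_flanks(label: str) -> str:
    """Context channel -> class channel, preserving a strand prefix."""
    strand = None
    if ":" in label:
        strand, label = label.split(":", 1)
    ref_ctx, alt_ctx = label.split(">")
    core = f"{ref_ctx[1:3]}>{alt_ctx[1:3]}"
    return f"{strand}:{core}" if strand else core
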