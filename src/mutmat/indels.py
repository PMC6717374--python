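"""Small insertion / deletion channels.

Indels cannot be classified by flanking context alone (deleting one C from a
C-run has no unique flanking sequence), so they are classified by length,
repeat-unit count, homopolymer length and microhomology:

* 1 bp events are homopolymer events, reported by the pyrimidine partner of
  the inserted/deleted base (C or T) with the homopolymer run length as size
  (deletions count the deleted base, so their repeat size is never 0);
* longer events at repetitive regions are repeat events sized by the number
  of contiguous exact copies of the motif at the locus;
* deletions whose motif has no full extra copy but partially overlaps the
  flanking sequence are microhomology events sized by the longest overlap of
  a proper prefix (3' side) or suffix (5' side) of the deleted motif.
  Insertions are never classified as microhomology.

Events are left-aligned against the reference before classification and both
flanks are scanned, making the channel independent of how the caller placed
the indel inside a repeat tract.

Label grammar (``size`` bins are capped with a ``+``):
``"3:Del:R:2"``, ``"1:Ins:C:0"``, ``"5+:Del:M:4"``; strand-labeled:
``"T:3:Del:R:2"``; sequence-extended: ``"3:Del:R:2:ACA"``.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable

from .reference import StrandState
from .sbs import sbs_strand_label
from .util import (
    RefMismatchError,
    UnclassifiableError,
    is_pure_purine,
    is_pure_pyrimidine,
    revcomp,
)

INS = "INS"
DEL = "DEL"

STRAND_LABELS = ("T", "U", "B", "N", "Q")
LENGTH_CLASSES = ("1", "2", "3", "4", "5+")

DEL_REPEAT_CAP = 6  # deletion repeat sizes 1..5, 6+
INS_REPEAT_CAP = 5  # insertion repeat sizes 0..4, 5+
MH_CAP = 5          # microhomology lengths 1..4, 5+
LONG_INDEL_NOTICE = 100  # "small" conventionally means < 100 bp


@dataclass(frozen=True)
class IndelEvent:
    """One pure insertion or deletion on the reference strand.

    ``position``: 1-based first deleted base (DEL) or the base after which
    the insertion occurs (INS; 0 allowed for an insertion before base 1).
    """

    kind: str
    chromosome: str
    position: int
    motif: str


def _cap(n: int, cap: int) -> str:
    return str(n) if n < cap else f"{cap}+"


def _length_class(length: int) -> str:
    return str(length) if length < 5 else "5+"


def left_align(seq: str, position: int, motif: str, kind: str) -> tuple[int, str]:
    """Shift an indel to its left-most equivalent representation.

    For a deletion, ``seq[position-1 : position-1+len(motif)]`` must equal
    the motif.  Shifting rotates the motif, so e.g. a ``CAA`` deletion inside
    an ``ACAACA`` tract normalizes to the same event as the ``ACA`` deletion.
    """
    length = len(motif)
    if kind == DEL:
        i = position - 1
        while i > 0 and seq[i - 1] == motif[-1]:
            i -= 1
            motif = seq[i] + motif[:-1]
        return i + 1, motif
    j = position  # insertion point: motif goes in front of seq[j] (0-based)
    while j > 0 and seq[j - 1] == motif[-1]:
        motif = seq[j - 1] + motif[:-1]
        j -= 1
    return j, motif


def count_repeat_units(seq: str, position: int, motif: str, kind: str) -> int:
    """Number of contiguous exact copies of the motif tiling the reference on
    both sides of the event site, plus the deleted copy itself for deletions
    (hence >= 1 for deletions, possibly 0 for insertions).  For 1 bp events
    this is the homopolymer run length."""
    length = len(motif)
    if kind == DEL:
        start = position - 1          # deleted span seq[start : start+length]
        after = start + length
    else:
        start = position              # insertion point, 0-based
        after = position
    n = 1 if kind == DEL else 0
    k = after
    while seq[k : k + length] == motif:
        n += 1
        k += length
    k = start - length
    while k >= 0 and seq[k : k + length] == motif:
        n += 1
        k -= length
    return n


def microhomology_length(seq: str, position: int, motif: str) -> int:
    """Longest partial overlap of a deleted motif with its flanks: the max of
    the longest proper prefix of the motif matching the reference immediately
    3' of the deletion and the longest proper suffix matching immediately 5'.
    """
    length = len(motif)
    start = position - 1
    after = start + length
    prefix = 0
    while (
        prefix + 1 < length
        and after + prefix < len(seq)
        and seq[after + prefix] == motif[prefix]
    ):
        prefix += 1
    suffix = 0
    while (
        suffix + 1 < length
        and start - suffix - 1 >= 0
        and seq[start - suffix - 1] == motif[length - suffix - 1]
    ):
        suffix += 1
    return max(prefix, suffix)


def indel_strand_label(state: StrandState, motif: str) -> str:
    """Strand label for an indel: N outside transcribed regions; Q for
    motifs mixing purines and pyrimidines inside them; otherwise oriented on
    the strand carrying the pyrimidine version of the motif."""
    if state == StrandState.NONTRANSCRIBED:
        return "N"
    if not (is_pure_pyrimidine(motif) or is_pure_purine(motif)):
        return "Q"
    if state == StrandState.BIDIRECTIONAL:
        return "B"
    return sbs_strand_label(state, is_pure_purine(motif))


def classify_indel(
    seq: str,
    state_at: Callable[[int], StrandState],
    event: IndelEvent,
) -> tuple[str, str, str]:
    """Classify one indel: returns (strand-labeled ID-415 label, ID-83 core
    label, sequence-extended label).

    ``state_at`` maps a 1-based position to a strand state; it is queried at
    the left-aligned first affected base so that equivalent representations
    classify identically.
    """
    motif = event.motif
    if not motif or set(motif) - set("ACGT"):
        raise UnclassifiableError("n_allele", f"unclassifiable motif {motif!r}")
    if event.kind == DEL:
        observed = seq[event.position - 1 : event.position - 1 + len(motif)]
        if observed != motif:
            raise RefMismatchError(f"reference is {observed!r}, record deletes {motif!r}")
    position, motif = left_align(seq, event.position, motif, event.kind)
    length = len(motif)
    kind = "Del" if event.kind == DEL else "Ins"
    lc = _length_class(length)
    n = count_repeat_units(seq, position, motif, event.kind)
    cap = DEL_REPEAT_CAP if event.kind == DEL else INS_REPEAT_CAP

    if length == 1:
        sub = "C" if motif in "CG" else "T"
        core = f"1:{kind}:{sub}:{_cap(n, cap)}"
    elif event.kind == DEL and n == 1:
        mh = microhomology_length(seq, position, motif)
        if mh >= 1:
            core = f"{lc}:Del:M:{_cap(mh, MH_CAP)}"
        else:
            core = f"{lc}:Del:R:1"
    else:
        core = f"{lc}:{kind}:R:{_cap(n, cap)}"

    site = position if event.kind == DEL else min(position + 1, len(seq))
    site = max(site, 1)
    strand = indel_strand_label(state_at(site), motif)
    return f"{strand}:{core}", core, extend_sequence_channel(core, motif)


def extend_sequence_channel(core: str, motif: str) -> str:
    """Append the canonical motif (lexicographically smaller of motif and its
    reverse complement) to homopolymer/repeat channels of motif length <= 4;
    microhomology and 5+ channels pass through unextended."""
    lc, _, sub, _ = core.split(":")
    if sub == "M" or lc == "5+":
        return core
    return f"{core}:{min(motif, revcomp(motif))}"


# ---- channel enumerations ------------------------------------------------

def _del_sizes() -> list[str]:
    return [_cap(i, DEL_REPEAT_CAP) for i in range(1, DEL_REPEAT_CAP + 1)]


def _ins_sizes() -> list[str]:
    return [_cap(i, INS_REPEAT_CAP) for i in range(0, INS_REPEAT_CAP + 1)]


def _mh_sizes(lc: str) -> list[str]:
    if lc == "5+":
        return [_cap(i, MH_CAP) for i in range(1, MH_CAP + 1)]
    return [str(i) for i in range(1, int(lc))]


def enumerate_id83() -> list[str]:
    labels = []
    for sub in ("C", "T"):
        labels += [f"1:Del:{sub}:{s}" for s in _del_sizes()]
    for sub in ("C", "T"):
        labels += [f"1:Ins:{sub}:{s}" for s in _ins_sizes()]
    for lc in ("2", "3", "4", "5+"):
        labels += [f"{lc}:Del:R:{s}" for s in _del_sizes()]
    for lc in ("2", "3", "4", "5+"):
        labels += [f"{lc}:Ins:R:{s}" for s in _ins_sizes()]
    for lc in ("2", "3", "4", "5+"):
        labels += [f"{lc}:Del:M:{s}" for s in _mh_sizes(lc)]
    return labels


def _canonical_motifs(length: int) -> list[str]:
    return sorted(
        {min(m, revcomp(m)) for m in ("".join(p) for p in product("ACGT", repeat=length))}
    )


def enumerate_id8628() -> list[str]:
    """The sequence-extended channel set implied by the extension rule."""
    labels = []
    for core in enumerate_id83():
        lc, kind, sub, size = core.split(":")
        if sub == "M" or lc == "5+":
            labels.append(core)
        elif lc == "1":
            motif = "C" if sub == "C" else "A"  # canonical of C/G and T/A
            labels.append(f"{core}:{motif}")
        else:
            labels += [f"{core}:{m}" for m in _canonical_motifs(int(lc))]
    return labels


def id28_label(core: str) -> str:
    """Collapse an ID-83 core into the 28-cell summary: kind x length class
    (with 1 bp split by pyrimidine base) x small/large size at the middle
    bin, plus deletion-microhomology cells by length class."""
    lc, kind, sub, size = core.split(":")
    if sub == "M":
        return f"Del:M:{lc}"
    cls = sub if lc == "1" else lc
    small = {"0", "1", "2"} if kind == "Ins" else {"1", "2", "3"}
    return f"{kind}:{cls}:{'small' if size in small else 'large'}"


def enumerate_id28() -> list[str]:
    labels = [
        f"{kind}:{cls}:{sz}"
        for kind in ("Del", "Ins")
        for cls in ("C", "T", "2", "3", "4", "5+")
        for sz in ("small", "large")
    ]
    labels += [f"Del:M:{lc}" for lc in ("2", "3", "4", "5+")]
    return labels


def enumerate_channels(scheme: str) -> list[str]:
    if scheme == "ID83":
        return enumerate_id83()
    if scheme == "ID28":
        return enumerate_id28()
    if scheme == "ID8628":
        return enumerate_id8628()
    if scheme == "ID415":
        return [f"{s}:{core}" for core in enumerate_id83() for s in STRAND_LABELS]
    raise KeyError(f"unknown ID scheme {scheme!r}")


# ---- collapse label maps -------------------------------------------------

def strip_strand(label: str) -> str:
    return label.split(":", 1)[1]


def strip_motif(label: str) -> str:
    parts = label.split(":")
    return ":".join(parts[:4]) if len(parts) == 5 else label
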