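"""Shared small helpers: alphabet, reverse complement, error types."""
from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
DNA = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


def is_pure_pyrimidine(seq: str) -> bool:
    return bool(seq) and set(seq) <= PYRIMIDINES


def is_pure_purine(seq: str) -> bool:
    return bool(seq) and set(seq) <= PURINES


class ClassificationError(Exception):
    """A mutation that cannot be assigned to any channel.

    ``reason`` is a short machine-readable tag used in the run log
    (e.g. ``ref_mismatch``, ``n_allele``).
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class RefMismatchError(ClassificationError):
    def __init__(self, message: str | None = None):
        super().__init__("ref_mismatch", message)


class UnclassifiableError(ClassificationError):
    pass
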