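"""The classic indel classification examples, end to end.

A deletion of ACA next to a second ACA copy is a length-3 deletion at a
repeat of 2 units; an insertion of CCTG into non-repeated sequence is a
length-4 insertion at a repeat of 0; a TAGTC deletion beside a TAGT overlap
is a length-5 deletion at a 4 bp microhomology.
"""
from mutmat.indels import DEL, INS, IndelEvent, classify_indel
from mutmat.reference import StrandState

NON = StrandState.NONTRANSCRIBED

cases = [
    ("ATTACAACAGGCGC", IndelEvent(DEL, "1", 4, "ACA"), "two adjacent ACA copies"),
    ("ATTACAGGCGC", IndelEvent(INS, "1", 6, "CCTG"), "no flanking repeat"),
    ("ACCCATAGTCTAGTAGCGGC", IndelEvent(DEL, "1", 6, "TAGTC"), "3' TAGT overlap"),
    ("ACCCAGTCTAGTCAAGCGGC", IndelEvent(DEL, "1", 9, "TAGTC"), "5' AGTC overlap"),
    ("ATCCCCCG", IndelEvent(DEL, "1", 3, "C"), "C deleted from a 5-run"),
]
for seq, event, note in cases:
    stranded, core, extended = classify_indel(seq, lambda p: NON, event)
    print(f"{event.kind:>3} {event.motif:<5} in {seq:<22} -> {core:<14} ({note})")

# Channel grammar: length : Del/Ins : subtype : size, where subtype C/T is a
# homopolymer event by pyrimidine base, R a repeat event sized in motif
# copies, and M a deletion at a microhomology sized by the overlap length.
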