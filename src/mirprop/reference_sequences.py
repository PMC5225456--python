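"""Reference sequences for the miR-218 validation assays.

The 50-nt 3′UTR fragments cloned downstream of Renilla luciferase for the
eight predicted miR-218 targets, and the mimic/scramble oligos used in the
transfections.  The mimic is the mature rno-miR-218a-5p sequence written
in DNA; its seed (positions 2–8) is TGTGCTT, so the canonical target-site
motifs are AAGCACA (7mer-m8), AGCACAA (7mer-A1) and AAGCACAA (8mer).
"""

from __future__ import annotations

from .io_formats import SequenceRecord, make_sequence_record

MIR218_MIMIC: str = "TTGTGCTTGATCTAACCATGT"
SCRAMBLE: str = "GCAGTTATCACGTCTATGTTT"

#: 50-nt luciferase insert per target gene 3′UTR
UTR_INSERTS: dict[str, str] = {
    "Gabrb3": "CCTTTATTTCTGTACTAACTTATCTCATAAGCACACCCAATTCCTCCTAG",
    "GluR2": "TATTGTTAGTCTCTTGATTCATAATGACTTAAGCACACTTGACATCAACT",
    "Dnmt3a": "TTGGTTGTCTCTAGCCTGATCAGATAGGAGCACAAACAGGAACAGAATAG",
    "Ube3a": "TCTTTGTAGCTGGACAGCACAATGTTTATGATTTATTTAATCTGTAGTTT",
    "Nrxn1": "AAACTTATTTACTTTCCTTTTTATGAAGCACATACAAAAGAAGACAGGGA",
    "Sema6b": "CGGGTGGGGATCTCCTCGCCACAGGGAAGCACAAGAGCCCCCTCCATCCC",
    "Gng3": "CGCACTTATCCTGAGATTATCTGAAGCACAAGGCCCTCCTTACCCACCTC",
    "Mecp2": "TTGGGATGTTTTTCTTACCGACAAGCACAGTCAGGTTGAAGACCTAACCA",
}


def mir218_record() -> SequenceRecord:
    return make_sequence_record("miR-218", MIR218_MIMIC, "DNA")


def insert_records() -> list[SequenceRecord]:
    return [
        make_sequence_record(name, seq, "DNA") for name, seq in UTR_INSERTS.items()
    ]
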