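"""Standard genetic code helpers shared by the evolution and simulation modules."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))
NUCLEOTIDES = "ACGT"


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or ``*`` for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def translate_cds(seq: str, strip_stop: bool = True) -> str:
    """Translate an in-frame CDS; a single terminal stop is stripped."""
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not a multiple of 3")
    aas = []
    for i in range(0, len(seq), 3):
        aa = translate_codon(seq[i:i + 3])
        if aa == "*":
            if strip_stop and i == len(seq) - 3:
                break
            raise ValueError(f"internal stop codon at nucleotide {i + 1}")
        aas.append(aa)
    return "".join(aas)


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError("sequence length not a multiple of 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]
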