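"""Small shared helpers: complementation, translation, interval checks."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code, DNA codons.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a DNA string in frame 0; incomplete final codon dropped.

    Codons containing N (or other non-ACGT characters) translate to 'X';
    stop codons to '*'.
    """
    out = []
    for i in range(0, len(dna) - 2, 3):
        out.append(GENETIC_CODE.get(dna[i:i + 3], "X"))
    return "".join(out)


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and (
        (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
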