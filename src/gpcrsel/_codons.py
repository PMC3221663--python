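"""Shared genetic-code tables for the 61-state sense-codon alphabet.

The standard nuclear genetic code is used throughout; the three stop codons
(TAA, TAG, TGA) are excluded from the state space.
"""
from __future__ import annotations

import numpy as np

NUCLEOTIDES = "TCAG"

_CODON_TABLE = {}
_BASES = {
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
_CODON_TABLE.update(_BASES)

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if _CODON_TABLE[a + b + c] != "*"
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = {c: _CODON_TABLE[c] for c in _CODON_TABLE}

GAP_CODON = "---"

_PURINES = {"A", "G"}


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) for a codon; '*' for stop."""
    return _CODON_TABLE[codon]


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


def _pair_tables():
    """Single-step codon-pair classification tables over the 61 sense codons.

    Returns boolean (61, 61) arrays: single-step adjacency, transition at the
    differing site, and synonymous change.
    """
    n = N_CODONS
    single = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            ts[i, j] = is_transition(ci[k], cj[k])
            syn[i, j] = translate_codon(ci) == translate_codon(cj)
    return single, ts, syn


SINGLE_STEP, TRANSITION, SYNONYMOUS = _pair_tables()
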