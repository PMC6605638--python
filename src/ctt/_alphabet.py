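"""Residue encodings shared by the alignment kernels.

Amino acids are indexed in BLOSUM62 order; index 24 is a mask sentinel
whose substitution score is strongly negative so masked stretches can
never participate in an alignment. DNA is encoded A,C,G,T -> 0..3 with
4 for any ambiguity code (N etc.); codons containing an ambiguous base
translate to X.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"  # BLOSUM62 order
AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
X_IDX = AA_INDEX["X"]
STOP_IDX = AA_INDEX["*"]
MASK_IDX = 24
MASK_SCORE = -10_000

_DNA_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_protein(residues: str) -> np.ndarray:
    """Encode a protein string as int8 indices (unknown letters -> X)."""
    return np.array([AA_INDEX.get(c, X_IDX) for c in residues], dtype=np.int8)


def encode_dna(seq: str) -> np.ndarray:
    return np.array([_DNA_INDEX.get(c, 4) for c in seq], dtype=np.int8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=8)
def substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """25x25 int32 substitution matrix in AA_ALPHABET order + mask row/col."""
    blosum = substitution_matrices.load(name)
    n = len(AA_ALPHABET)
    mat = np.full((n + 1, n + 1), MASK_SCORE, dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            mat[i, j] = int(blosum[a][b])
    return mat


@lru_cache(maxsize=1)
def codon_table() -> np.ndarray:
    """Map codon index (25*b0 + 5*b1 + b2 over the 5-letter DNA code) to an
    amino-acid index; any codon touching an ambiguous base yields X."""
    table = np.full(125, X_IDX, dtype=np.int8)
    bases = "ACGT"
    for i0, b0 in enumerate(bases):
        for i1, b1 in enumerate(bases):
            for i2, b2 in enumerate(bases):
                aa = str(Seq(b0 + b1 + b2).translate())
                table[25 * i0 + 5 * i1 + i2] = AA_INDEX[aa]
    return table


def translate_cds(cds: str) -> str:
    """Translate a DNA string codon-by-codon; trailing partial codon dropped,
    stops rendered '*', N-containing codons rendered 'X'."""
    tab = codon_table()
    enc = encode_dna(cds)
    n = len(enc) // 3
    out = []
    for i in range(n):
        c = enc[3 * i : 3 * i + 3]
        out.append(AA_ALPHABET[tab[25 * c[0] + 5 * c[1] + c[2]]])
    return "".join(out)
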