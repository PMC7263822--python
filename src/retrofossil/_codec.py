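"""Nucleotide encoding and translation helpers shared across modules.

Sequences cross module boundaries as plain uppercase ACGT strings; the
simulation and alignment engines work on uint8 code arrays (A=0, C=1, G=2,
T=3) internally.
"""
from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
A, C, G, T = 0, 1, 2, 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# codon -> amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _v in AA_TO_CODONS.values():
    _v.sort()

# codon index (16*b0 + 4*b1 + b2, codes) -> amino acid, as a lookup array
AA_BY_CODON_INDEX = np.empty(64, dtype="<U1")
for _i in range(64):
    _codon = BASES[_i >> 4] + BASES[(_i >> 2) & 3] + BASES[_i & 3]
    AA_BY_CODON_INDEX[_i] = CODON_TO_AA[_codon]

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _i


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if codes.size and codes.max() > 3:
        bad = seq[int(np.argmax(codes > 3))]
        raise InvalidSequenceError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate complete codons of ``seq`` (frame 0); stops are '*'.

    A trailing partial codon is ignored.
    """
    n = len(seq) // 3
    return "".join(CODON_TO_AA[seq[3 * i : 3 * i + 3]] for i in range(n))


def is_stop_codon(c0: int, c1: int, c2: int) -> bool:
    """Stop test on base codes: TAA, TAG, TGA."""
    return c0 == T and ((c1 == A and (c2 == A or c2 == G)) or (c1 == G and c2 == A))


def stop_flags(codes: np.ndarray) -> np.ndarray:
    """Boolean per-full-codon stop flags for a code array (frame 0)."""
    n_full = codes.size // 3
    cod = codes[: 3 * n_full].reshape(n_full, 3)
    return (cod[:, 0] == T) & (
        ((cod[:, 1] == A) & ((cod[:, 2] == A) | (cod[:, 2] == G)))
        | ((cod[:, 1] == G) & (cod[:, 2] == A))
    )
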