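"""Base and dinucleotide encodings shared across modules.

Bases are coded A=0, C=1, G=2, T=3, N=4. A dinucleotide (b1, b2) has index
``4*b1 + b2`` in the lexicographic order AA, AC, ..., TT.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BASES", "N_CODE", "DINUCLEOTIDES", "DINUC_INDEX", "RC_PERMUTATION",
    "encode", "decode", "dinucleotide_codes", "expand_iupac_dinucleotide",
]

BASES = "ACGT"
N_CODE = 4
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Row permutation mapping a dinucleotide index to its reverse complement's.
RC_PERMUTATION = np.array(
    [DINUC_INDEX[_COMP[d[1]] + _COMP[d[0]]] for d in DINUCLEOTIDES],
    dtype=np.intp,
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "S": "GC", "R": "AG", "Y": "CT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def encode(seq: str) -> np.ndarray:
    """String -> int8 codes (N and anything non-ACGT -> 4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def dinucleotide_codes(codes: np.ndarray) -> np.ndarray:
    """Per-step dinucleotide indices; steps touching an N get -1.

    Works on 1-D (length L) or 2-D (n x L) code arrays; output has L-1 steps.
    """
    b1 = codes[..., :-1]
    b2 = codes[..., 1:]
    out = 4 * b1.astype(np.int16) + b2
    out[(b1 >= N_CODE) | (b2 >= N_CODE)] = -1
    return out


def expand_iupac_dinucleotide(pattern: str) -> frozenset[str]:
    """Expand a 2-letter IUPAC pattern, e.g. 'WW' -> {AA, AT, TA, TT}."""
    if len(pattern) != 2 or any(c not in _IUPAC for c in pattern.upper()):
        raise ValueError(f"not a 2-letter IUPAC dinucleotide: {pattern!r}")
    p = pattern.upper()
    return frozenset(a + b for a in _IUPAC[p[0]] for b in _IUPAC[p[1]])
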