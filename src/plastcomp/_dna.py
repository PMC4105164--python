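"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: base -> 2-bit code used for vectorised k-mer work; N gets its own code.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


def gc_fraction(seq: str) -> float:
    """GC fraction with N excluded from the denominator."""
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    return gc / denom if denom else 0.0
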