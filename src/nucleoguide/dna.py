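"""Small DNA-string helpers shared across modules.

Sequences are plain uppercase Python strings over A/C/G/T/N; numpy byte
views are used only inside the hot scanning loops.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes (no copy of semantics)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def iupac_match(base: str, code: str) -> bool:
    """True if concrete `base` is matched by IUPAC `code`."""
    return base in IUPAC[code]


def matches_pattern(seq: str, pattern: str) -> bool:
    """Match a concrete sequence against an IUPAC pattern of equal length."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq, pattern))


def pattern_mask(arr: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean mask over positions i where arr[i : i+len(pattern)] matches `pattern`.

    Positions within len(pattern)-1 of the array end are False.
    """
    n, k = arr.size, len(pattern)
    mask = np.zeros(n, dtype=bool)
    if n < k:
        return mask
    ok = np.ones(n - k + 1, dtype=bool)
    for j, code in enumerate(pattern):
        allowed = np.frombuffer(IUPAC[code].encode("ascii"), dtype=np.uint8)
        ok &= np.isin(arr[j : j + n - k + 1], allowed)
    mask[: n - k + 1] = ok
    return mask
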