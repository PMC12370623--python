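"""Low-level DNA utilities: IUPAC alphabet, reverse complement, vectorised motif matching.

Genome sequences are upper-case strings over {A,C,G,T,N}. An ``N`` in the
genome matches no pattern letter (not even pattern ``N``): ambiguous bases
never anchor a guide.
"""

from __future__ import annotations

import numpy as np

#: IUPAC nucleotide codes -> the set of concrete bases each one stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP_TABLE = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; handles IUPAC ambiguity codes."""
    return seq.translate(_COMP_TABLE)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes (no copy of content)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_LUTS: dict[str, np.ndarray] = {}


def _lut(letter: str) -> np.ndarray:
    """256-entry boolean lookup table: which ASCII codes satisfy one IUPAC letter."""
    try:
        return _LUTS[letter]
    except KeyError:
        lut = np.zeros(256, dtype=bool)
        for base in IUPAC[letter]:
            lut[ord(base)] = True
        _LUTS[letter] = lut
        return lut


def match_positions(arr: np.ndarray, pattern: str) -> np.ndarray:
    """All start positions where ``pattern`` (IUPAC) matches, on the given axis.

    Vectorised: one boolean mask per pattern letter, AND-ed with shifted views.
    """
    n = arr.size
    length = len(pattern)
    if n < length:
        return np.empty(0, dtype=np.int64)
    mask = _lut(pattern[0])[arr[: n - length + 1]]
    for i in range(1, length):
        mask = mask & _lut(pattern[i])[arr[i : n - length + 1 + i]]
    return np.nonzero(mask)[0]


def pam_anchor_positions(arr: np.ndarray, pattern: str, strand: str) -> np.ndarray:
    """Anchor positions (forward axis) of PAM matches on one strand.

    The *anchor* is the genomic position of the PAM-proximal protospacer base,
    i.e. the base immediately 5' of the PAM on the PAM-bearing strand. On the
    minus strand a PAM written 5'->3' occupies forward interval
    ``[anchor - len, anchor)`` as the reverse complement of the pattern.
    """
    length = len(pattern)
    if strand == "+":
        return match_positions(arr, pattern) - 1
    return match_positions(arr, revcomp(pattern)) + length
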