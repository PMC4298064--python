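"""2-bit integer codec for DNA k-mers.

Every k-mer over {A, C, G, T} maps to an integer in [0, 4**k) by
concatenating 2-bit base codes big-endian (first base most significant).
The mapping is fixed to

    A = 00, C = 01, G = 10, T = 11

so that complementation is bitwise inversion of each 2-bit field: the
reverse complement of a code is the field-reversal of ``code XOR mask``
where ``mask`` has all 2k low bits set. This constant-time complementation
is the reason the mapping is normative for the whole package; it is also
recorded in the profile container header on disk.

k is capped at 15 so codes stay below 2**30 and dense count vectors of
length 4**k remain addressable.
"""

from __future__ import annotations

import numpy as np

MAX_K = 15

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")


def encode(sequence: str) -> int:
    """Encode a DNA string of length k as its integer k-mer code.

    Case-insensitive; any character outside {A, C, G, T} is an error —
    callers must split on ambiguity codes before encoding.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    _check_k(len(sequence))
    code = 0
    for base in sequence.upper():
        try:
            code = (code << 2) | _BASE_TO_CODE[base]
        except KeyError:
            raise ValueError(f"non-ACGT character {base!r} in {sequence!r}") from None
    return code


def decode(code: int, k: int) -> str:
    """Decode an integer k-mer code back to its DNA string (inverse of encode)."""
    _check_k(k)
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    bases = []
    for shift in range(2 * (k - 1), -1, -2):
        bases.append(_CODE_TO_BASE[(code >> shift) & 3])
    return "".join(bases)


def reverse_complement(code: int, k: int) -> int:
    """Reverse complement of a k-mer code in O(k) bit operations.

    Equivalent to encoding the reverse-complemented string of ``decode(code, k)``.
    """
    _check_k(k)
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    comp = code ^ (4**k - 1)  # complement every 2-bit field
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (comp & 3)
        comp >>= 2
    return rc


def reverse_complement_table(k: int) -> np.ndarray:
    """Permutation array ``t`` with ``t[code] == reverse_complement(code, k)``.

    Vectorized over all 4**k codes; used by profile-level strand operations.
    """
    _check_k(k)
    comp = np.arange(4**k, dtype=np.int64) ^ (4**k - 1)
    rc = np.zeros(4**k, dtype=np.int64)
    for _ in range(k):
        rc = (rc << 2) | (comp & 3)
        comp >>= 2
    return rc
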