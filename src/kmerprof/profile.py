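"""k-mer profiles: construction by sliding-window counting and profile algebra.

A :class:`Profile` is a dense vector of 4**k counts indexed by k-mer code
(see :mod:`kmerprof.codec`), together with the word length ``k`` and a
dataset label. It is the central object of the package: all transforms and
distances operate on profiles.

Counting slides a window of size k along each input record. Windows never
span record boundaries, and windows containing any non-ACGT character are
skipped — equivalently, each record is split into maximal ACGT-only
fragments and each fragment of length L >= k contributes L - k + 1 windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .codec import MAX_K, reverse_complement_table

_ACGT_FRAGMENT = re.compile(r"[ACGT]+")

_BASE_VALUES = np.full(256, -1, dtype=np.int8)
for _b, _v in zip(b"ACGT", range(4)):
    _BASE_VALUES[_b] = _v


class SequenceRecord(NamedTuple):
    """A named DNA sequence (FASTA record carrier); may contain ambiguity codes."""

    identifier: str
    sequence: str


@dataclass
class Profile:
    """Dense k-mer count vector with label.

    counts has length exactly 4**k. Counts are integral after counting and
    merging but may become non-integral reals after scaling.
    """

    k: int
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (4**self.k,):
            raise ValueError(
                f"counts must have length 4**{self.k}={4**self.k}, "
                f"got shape {self.counts.shape}"
            )

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def non_zero(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def nullomers(self) -> int:
        return 4**self.k - self.non_zero

    def copy(self, label: str | None = None) -> "Profile":
        return Profile(self.k, self.counts.copy(), self.label if label is None else label)

    @classmethod
    def zeros(cls, k: int, label: str = "") -> "Profile":
        return cls(k, np.zeros(4**k, dtype=np.uint64), label)


def _fragment_codes(fragment: str, k: int) -> np.ndarray:
    """Codes of all length-k windows of an ACGT-only fragment (len >= k)."""
    vals = _BASE_VALUES[np.frombuffer(fragment.encode("ascii"), dtype=np.uint8)]
    n = len(fragment) - k + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = (codes << 2) | vals[j : j + n]
    return codes


def count(records: Iterable[SequenceRecord], k: int, label: str = "") -> Profile:
    """Count all k-mers in a stream of records into a fresh profile.

    Streaming: memory use is bounded by the 4**k count vector regardless of
    input size. Records shorter than k contribute nothing.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    counts = np.zeros(4**k, dtype=np.uint64)
    for record in records:
        for fragment in _ACGT_FRAGMENT.findall(record.sequence.upper()):
            if len(fragment) >= k:
                codes = _fragment_codes(fragment, k)
                counts += np.bincount(codes, minlength=4**k).astype(np.uint64)
    return Profile(k, counts, label)


def merge(a: Profile, b: Profile, label: str | None = None) -> Profile:
    """Element-wise sum of two profiles of the same k (e.g. paired-end mates)."""
    if a.k != b.k:
        raise ValueError(f"cannot merge profiles with k={a.k} and k={b.k}")
    if label is None:
        label = f"{a.label}+{b.label}" if a.label or b.label else ""
    return Profile(a.k, a.counts + b.counts, label)


def shrink(p: Profile, m: int) -> Profile:
    """Project a k-profile down to word length m < k.

    Each collapse step k -> k-1 sums the 4 counts sharing a (k-1)-prefix,
    i.e. consecutive blocks of 4 in code order; repeated until length m.
    The total count is conserved. Note the word-boundary effect: a single
    read of length L has L-k+1 windows at size k but L-m+1 at size m, so a
    shrunk profile undercounts terminal windows relative to direct counting.
    """
    if not 1 <= m < p.k:
        raise ValueError(f"target word length must satisfy 1 <= m < k={p.k}, got {m}")
    counts = p.counts.reshape(4**m, 4 ** (p.k - m)).sum(axis=1)
    return Profile(m, counts, p.label)


def balance(p: Profile) -> Profile:
    """Strand-symmetrize: new[w] = counts[w] + counts[rc(w)] for every code w.

    Palindromic k-mers (their own reverse complement) are doubled. The
    result satisfies new[w] == new[rc(w)] everywhere, so its strand balance
    statistic is exactly 0.
    """
    rc = reverse_complement_table(p.k)
    return Profile(p.k, p.counts + p.counts[rc], p.label)


def shuffle(p: Profile, seed: int) -> Profile:
    """Randomly permute the count vector (zeros included).

    The multiset of count values — including the nullomer mass — is
    preserved, giving a random profile with the same count distribution.
    """
    rng = np.random.default_rng(seed)
    return Profile(p.k, rng.permutation(p.counts), p.label)


def info(p: Profile) -> dict:
    """Summary statistics: k, total, non-zero / nullomer counts, count moments."""
    counts = p.counts.astype(np.float64)
    return {
        "k": p.k,
        "label": p.label,
        "total": p.total,
        "non_zero": p.non_zero,
        "nullomers": p.nullomers,
        "mean": float(counts.mean()),
        "median": float(np.median(counts)),
        "sd": float(counts.std(ddof=0)),
    }


def spectrum(p: Profile, include_zero: bool = False) -> dict[int, int]:
    """Frequency-of-frequencies table: count c -> number of k-mers seen c times.

    The modality of this distribution reflects the complexity of the
    sequenced material. Requires integral counts (rejects scaled profiles).
    """
    counts = p.counts
    if not np.all(counts == np.floor(counts)):
        raise ValueError("spectrum requires integral counts (profile was scaled?)")
    ints = counts.astype(np.int64)
    freq = np.bincount(ints)
    table = {c: int(n) for c, n in enumerate(freq) if n > 0 and (c > 0 or include_zero)}
    return table
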