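"""Multiset distance between k-mer profiles, strand balance and distance matrices.

The dissimilarity between two profiles is a multiset distance: a pairwise
function f over the two counts of each k-mer, summed over every position
where at least one profile is nonzero, and normalized by the number of such
positions plus one (the +1 guards the empty set and keeps values below 1
for the default f). The default per-position function is

    f(x, y) = |x - y| / ((x + 1) (y + 1))

which is symmetric, zero on equal counts, bounded below 1, and weights a
discrepancy more heavily when the counts involved are small — exactly the
rare-k-mer regime where library artefacts (chimeras, errors, contamination)
show up.

Strand balance applies the same distance to the two halves of one profile:
the sub-profile of k-mers versus the sub-profile of their reverse
complements. 0 means perfectly strand-balanced coverage; a deeply sequenced
unbiased library approaches 0 as both strands are sampled evenly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .codec import reverse_complement_table
from .profile import Profile
from .transforms import SmoothingPolicy, prepare_pair

PairwiseFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]


def pairwise_default(x, y):
    """Default per-k-mer distance |x - y| / ((x + 1)(y + 1)); vectorized."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    result = np.abs(x - y) / ((x + 1.0) * (y + 1.0))
    return result if result.ndim else float(result)


def _multiset(x: np.ndarray, y: np.ndarray, f: PairwiseFunction) -> float:
    """Multiset distance between two aligned non-negative vectors."""
    mask = (x != 0) | (y != 0)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    # fixed (index) order accumulation for bit-reproducibility
    return float(np.sum(f(x[mask], y[mask]))) / (n + 1)


def multiset_distance(
    a: Profile, b: Profile, f: PairwiseFunction = pairwise_default
) -> float:
    """Multiset distance between two profiles of the same k.

    Sums f over positions where either profile is nonzero, divided by
    (number of such positions + 1). 0 for identical profiles; < 1 with the
    default f.
    """
    if a.k != b.k:
        raise ValueError(f"profiles have different k: {a.k} vs {b.k}")
    return _multiset(
        np.asarray(a.counts, dtype=np.float64),
        np.asarray(b.counts, dtype=np.float64),
        f,
    )


def strand_balance(p: Profile, f: PairwiseFunction = pairwise_default) -> float:
    """Distance between the k-mer sub-profile and its reverse-complement mirror.

    Pairs every code w with rc(w) for w strictly below its reverse
    complement; palindromes are excluded (their self-pair contributes 0 to
    the numerator but would inflate the position count, diluting the
    statistic). Returns 0 exactly when counts[w] == counts[rc(w)] for all
    non-palindromic w.
    """
    rc = reverse_complement_table(p.k)
    codes = np.arange(4**p.k)
    forward = codes < rc
    x = np.asarray(p.counts, dtype=np.float64)[forward]
    y = np.asarray(p.counts, dtype=np.float64)[rc[forward]]
    return _multiset(x, y, f)


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise profile distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def distance_matrix(
    profiles: Sequence[Profile],
    do_balance: bool = False,
    do_smooth: bool = False,
    policy: SmoothingPolicy | None = None,
    do_scale: bool = False,
    f: PairwiseFunction = pairwise_default,
) -> DistanceMatrix:
    """All-vs-all distances with per-pair transforms.

    For each unordered pair the transform pipeline (balance -> smooth ->
    scale, per flags) runs on fresh copies, so transforms never mutate the
    inputs or leak state between pairs. Results are independent of input
    order up to the corresponding label permutation.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"profiles have mixed k: {sorted(ks)}")
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = prepare_pair(
                profiles[i],
                profiles[j],
                do_balance=do_balance,
                do_smooth=do_smooth,
                policy=policy,
                do_scale=do_scale,
            )
            values[i, j] = values[j, i] = multiset_distance(a, b, f)
    labels = [p.label or f"profile_{i}" for i, p in enumerate(profiles)]
    return DistanceMatrix(labels, values)


def median_pairwise_distance(m: DistanceMatrix) -> dict[str, float]:
    """Median off-diagonal distance per sample; high values flag outliers."""
    n = len(m.labels)
    if n < 3:
        raise ValueError("need at least 3 samples for per-sample medians")
    out = {}
    for i, label in enumerate(m.labels):
        row = np.delete(m.values[i], i)
        out[label] = float(np.median(row))
    return out
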