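"""Pairwise transforms that make profiles of different library sizes comparable.

Two complementary normalizations:

* **scaling** — a global correction: the profile with the smaller total is
  multiplied up so both totals ("areas under the curve") match. Scaling up,
  never down, preserves the resolution of the larger library.

* **dynamic smoothing** — a local correction: wherever counts are weak in
  either profile, groups of 4 sibling k-mers (sharing a (k-1)-prefix) are
  merged to the shorter word length, jointly in both profiles so positions
  remain comparable. This targets the rare and absent k-mers that make
  distances sensitive to sequencing depth.

The canonical pairwise pipeline is balance -> smooth -> scale (each step
optional): smoothing must see the raw integer count structure, and scaling
last equalizes areas on the final block structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .profile import Profile
from . import profile as _profile

_SUMMARIES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "min": lambda blocks: blocks.min(axis=1),
    "max": lambda blocks: blocks.max(axis=1),
    "mean": lambda blocks: blocks.mean(axis=1),
    "median": lambda blocks: np.median(blocks, axis=1),
}


@dataclass(frozen=True)
class SmoothingPolicy:
    """Collapse rule for dynamic smoothing.

    ``summary`` reduces the 4 sibling block totals to one number (one of
    "min"/"max"/"mean"/"median", or a callable taking an (n, 4) array and
    returning n values); a group collapses when the summary is <= threshold
    in either profile. The default (min, 0) merges exactly the groups that
    contain a nullomer, matching the rationale that rare and absent k-mers
    drive library-size sensitivity.
    """

    summary: str | Callable[[np.ndarray], np.ndarray] = "min"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if isinstance(self.summary, str) and self.summary not in _SUMMARIES:
            raise ValueError(
                f"summary must be one of {sorted(_SUMMARIES)} or a callable, "
                f"got {self.summary!r}"
            )

    def reduce(self, blocks: np.ndarray) -> np.ndarray:
        """Apply the summary along axis 1 of an (n_groups, 4) totals array."""
        if callable(self.summary):
            return np.asarray(self.summary(blocks), dtype=np.float64)
        return np.asarray(_SUMMARIES[self.summary](blocks), dtype=np.float64)


def scale_pair(a: Profile, b: Profile) -> tuple[Profile, Profile]:
    """Scale the smaller-total profile up so both totals match exactly.

    Returns fresh profiles; counts become floating point on the scaled side.
    """
    if a.k != b.k:
        raise ValueError(f"profiles have different k: {a.k} vs {b.k}")
    ta, tb = a.total, b.total
    if ta == 0 or tb == 0:
        raise ValueError("cannot scale a zero-total profile")
    if ta < tb:
        return Profile(a.k, a.counts * (tb / ta), a.label), b.copy()
    if tb < ta:
        return a.copy(), Profile(b.k, b.counts * (ta / tb), b.label)
    return a.copy(), b.copy()


def smooth_pair(
    a: Profile, b: Profile, policy: SmoothingPolicy | None = None
) -> tuple[Profile, Profile]:
    """Jointly smooth two profiles under one policy.

    Bottom-up over the quartary prefix tree: starting from singleton blocks
    at word length k, each group of 4 sibling blocks whose members are all
    fully collapsed is merged — in BOTH profiles — whenever the policy
    summary of its 4 block totals is <= threshold in either profile. A
    merged group stores its total at the lexicographically first code of
    the merged prefix block; the other positions become 0. Merging iterates
    upward only through groups newly merged and stops at word length 1 (the
    profile is never collapsed to a single bin).

    Per-profile totals are conserved, the final block partition is identical
    for both outputs, and the operation is idempotent for a fixed policy.
    """
    if a.k != b.k:
        raise ValueError(f"profiles have different k: {a.k} vs {b.k}")
    if policy is None:
        policy = SmoothingPolicy()
    k = a.k
    ca = a.counts.astype(np.float64, copy=True)
    cb = b.counts.astype(np.float64, copy=True)
    n = 4**k

    # collapsed[i] marks block i (of the current block size) as fully merged
    collapsed = np.ones(n, dtype=bool)  # singletons are trivially collapsed
    block = 1  # current block size; carriers sit at multiples of `block`
    for _level in range(k, 1, -1):
        n_groups = n // (4 * block)
        # carrier values = block totals; shape (n_groups, 4)
        carriers_a = ca.reshape(n_groups, 4, block)[:, :, 0]
        carriers_b = cb.reshape(n_groups, 4, block)[:, :, 0]
        eligible = collapsed.reshape(n_groups, 4).all(axis=1)
        cond = eligible & (
            (policy.reduce(carriers_a) <= policy.threshold)
            | (policy.reduce(carriers_b) <= policy.threshold)
        )
        if not cond.any():
            break
        for c, merged in ((ca, carriers_a), (cb, carriers_b)):
            view = c.reshape(n_groups, 4, block)
            totals = merged[cond].sum(axis=1)
            view[cond, :, 0] = 0.0
            view[cond, 0, 0] = totals
        collapsed = cond
        block *= 4
    fa = Profile(k, ca, a.label)
    fb = Profile(k, cb, b.label)
    return fa, fb


def prepare_pair(
    a: Profile,
    b: Profile,
    do_balance: bool = False,
    do_smooth: bool = False,
    policy: SmoothingPolicy | None = None,
    do_scale: bool = False,
) -> tuple[Profile, Profile]:
    """Apply the canonical pairwise pipeline: balance -> smooth -> scale.

    Each step is optional; the order is fixed. Inputs are never mutated.
    """
    if a.k != b.k:
        raise ValueError(f"profiles have different k: {a.k} vs {b.k}")
    if do_balance:
        a, b = _profile.balance(a), _profile.balance(b)
    else:
        a, b = a.copy(), b.copy()
    if do_smooth:
        a, b = smooth_pair(a, b, policy)
    if do_scale:
        a, b = scale_pair(a, b)
    return a, b
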