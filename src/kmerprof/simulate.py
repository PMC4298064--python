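"""Seeded generators for synthetic genomes, metagenome mixtures and reads.

These fixtures reproduce the statistical structure of modelled-metagenome
experiments without any external data: random genomes with controlled GC
content, divergent copies emulating closely related species, mixtures at
stated copy numbers, uniform shotgun reads with substitution errors, and
composition-preserving permutation controls used to choose the word
length k.

All generators are reproducible under fixed seeds. They are deliberately
simple — i.i.d. base composition, uniform read positions, i.i.d.
substitution errors — so expectations in tests have closed forms; they do
not emulate real error models (indels, quality-correlated errors) or real
abundance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .distance import multiset_distance
from .profile import Profile, SequenceRecord, count
from .transforms import scale_pair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def reverse_complement_str(sequence: str) -> str:
    return sequence.upper().encode().translate(_COMPLEMENT)[::-1].decode()


def random_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random DNA with P(G) + P(C) = gc_fraction, split evenly."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[draws].tobytes().decode()


def mutate_sequence(sequence: str, divergence: float = 0.1, seed: int = 0) -> str:
    """Divergent copy of a sequence: substitute a stated fraction of positions.

    Each selected position gets a uniformly chosen *different* base. With
    divergence 0.1 the result is ~90% identical to the input, emulating the
    homology of closely related bacterial species.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = np.frombuffer(sequence.upper().encode(), dtype=np.uint8).copy()
    hit = rng.random(len(vals)) < divergence
    # map base -> index, add 1..3 mod 4 to force a different base
    idx = np.searchsorted(_BASES, vals[hit])
    vals[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.sum())) % 4]
    return vals.tobytes().decode()


def permute_sequence(sequence: str, seed: int = 0) -> str:
    """Uniform random permutation of the characters (composition preserved).

    Destroys all word structure beyond single-base composition; the k = 1
    profile is exactly conserved while profiles at k >= 2 generally change.
    """
    if not sequence:
        raise ValueError("cannot permute an empty sequence")
    rng = np.random.default_rng(seed)
    vals = np.frombuffer(sequence.encode(), dtype=np.uint8)
    return rng.permutation(vals).tobytes().decode()


def repetitive_sequence(
    n_units: int = 20,
    unit_length: int = 500,
    spacer_length: int = 500,
    divergence: float = 0.02,
    seed: int = 0,
) -> str:
    """Repeat-structured synthetic sequence: diverged copies of one unit
    separated by random spacers, mimicking the repetitive and structural
    elements that give real genomes a multimodal k-mer spectrum."""
    rng = np.random.default_rng(seed)
    unit = random_genome(unit_length, seed=int(rng.integers(2**31)))
    parts = []
    for _ in range(n_units):
        parts.append(mutate_sequence(unit, divergence, int(rng.integers(2**31))))
        parts.append(random_genome(spacer_length, seed=int(rng.integers(2**31))))
    return "".join(parts)


@dataclass(frozen=True)
class MixtureSpec:
    """Metagenome mixture: labelled genomes at integer copy numbers."""

    genomes: Sequence[SequenceRecord]
    copy_numbers: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.genomes) != len(self.copy_numbers):
            raise ValueError("genomes and copy_numbers must have equal length")
        if any(c < 0 for c in self.copy_numbers):
            raise ValueError("copy numbers must be non-negative")
        if not any(c > 0 for c in self.copy_numbers):
            raise ValueError("at least one copy number must be positive")


def build_mixture(spec: MixtureSpec) -> list[SequenceRecord]:
    """Emit each genome repeated copy_number times (labels suffixed by copy).

    The k-mer profile of the result is exactly the integer combination
    sum_i copy_i * profile(genome_i), since records are counted independently.
    """
    records = []
    for genome, copies in zip(spec.genomes, spec.copy_numbers):
        for i in range(copies):
            records.append(SequenceRecord(f"{genome.identifier}_copy{i + 1}", genome.sequence))
    return records


@dataclass(frozen=True)
class ReadSimSpec:
    """Shotgun read simulation parameters.

    reverse_probability is the per-read chance of sampling the minus strand:
    0.5 models an unbiased library, 0.0 a single-strand (fully biased) one.
    """

    read_length: int = 100
    n_reads: int = 1000
    error_rate: float = 0.0
    paired: bool = False
    insert_size: int = 300
    reverse_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.reverse_probability <= 1:
            raise ValueError("reverse_probability must be in [0, 1]")
        if self.paired and self.insert_size < 2 * self.read_length:
            raise ValueError("insert_size must be >= 2 * read_length for paired reads")


def _apply_errors(vals: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0:
        return vals
    hit = rng.random(len(vals)) < error_rate
    idx = np.searchsorted(_BASES, vals[hit])
    out = vals.copy()
    out[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.sum())) % 4]
    return out


def simulate_reads(
    sequences: str | SequenceRecord | Sequence[SequenceRecord], spec: ReadSimSpec
) -> Iterator[SequenceRecord]:
    """Draw reads uniformly over positions (and sources, length-weighted).

    Single-end mode emits spec.n_reads reads; paired mode emits
    spec.n_reads fragments = 2 * n_reads mates, the second mate from the
    opposite strand at the far end of the insert. Substitution errors are
    i.i.d. per base at spec.error_rate.
    """
    if isinstance(sequences, str):
        sequences = [SequenceRecord("seq", sequences)]
    elif isinstance(sequences, SequenceRecord):
        sequences = [sequences]
    rng = np.random.default_rng(spec.seed)
    span = spec.insert_size if spec.paired else spec.read_length
    arrays = []
    for record in sequences:
        if len(record.sequence) < span:
            raise ValueError(
                f"source {record.identifier!r} shorter than {span} bases"
            )
        arrays.append(np.frombuffer(record.sequence.upper().encode(), dtype=np.uint8))
    # length-weighted source choice = uniform over all valid start positions
    starts_per_source = np.array([len(a) - span + 1 for a in arrays], dtype=np.float64)
    source_p = starts_per_source / starts_per_source.sum()
    for i in range(spec.n_reads):
        src = rng.choice(len(arrays), p=source_p)
        genome = arrays[src]
        start = int(rng.integers(0, len(genome) - span + 1))
        fragment = genome[start : start + span]
        reverse = rng.random() < spec.reverse_probability
        if spec.paired:
            left = fragment[: spec.read_length]
            right_rc = _rc_vals(fragment[-spec.read_length :])
            # mate 1 reads the 5' end of the sampled strand; mate 2 the far
            # end of the insert from the opposite strand
            m1, m2 = (right_rc, left) if reverse else (left, right_rc)
            m1 = _apply_errors(m1, spec.error_rate, rng)
            m2 = _apply_errors(m2, spec.error_rate, rng)
            yield SequenceRecord(f"read{i + 1}/1", m1.tobytes().decode())
            yield SequenceRecord(f"read{i + 1}/2", m2.tobytes().decode())
        else:
            read = _rc_vals(fragment) if reverse else fragment
            read = _apply_errors(read, spec.error_rate, rng)
            yield SequenceRecord(f"read{i + 1}", read.tobytes().decode())


_RC_LUT = np.zeros(256, dtype=np.uint8)
for _src, _dst in zip(b"ACGT", b"TGCA"):
    _RC_LUT[_src] = _dst


def _rc_vals(vals: np.ndarray) -> np.ndarray:
    return _RC_LUT[vals][::-1]


def scan_k(
    records: str | Sequence[SequenceRecord],
    k_min: int = 1,
    k_max: int = 8,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance of the data to composition-preserving permutation controls,
    per k.

    For each k in [k_min, k_max], profiles the data and n_permutations
    per-record shuffled versions and returns the mean and standard deviation
    of the data-vs-permuted distances (computed after scaling; permutation
    preserves totals, so scaling only absorbs window-boundary effects).
    The k that best separates real structure from permuted noise — where
    the curve rises then levels off — is a good profiling word length.
    """
    if not (1 <= k_min <= k_max <= 15):
        raise ValueError("need 1 <= k_min <= k_max <= 15")
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    if isinstance(records, str):
        records = [SequenceRecord("seq", records)]
    rng = np.random.default_rng(seed)
    permuted_sets = []
    for _ in range(n_permutations):
        permuted_sets.append(
            [
                SequenceRecord(r.identifier, permute_sequence(r.sequence, int(rng.integers(2**31))))
                for r in records
            ]
        )
    rows = []
    for k in range(k_min, k_max + 1):
        data_profile = count(records, k, label="data")
        distances = []
        for perm in permuted_sets:
            perm_profile = count(perm, k, label="permuted")
            a, b = scale_pair(data_profile, perm_profile)
            distances.append(multiset_distance(a, b))
        rows.append(
            {
                "k": k,
                "mean_distance": float(np.mean(distances)),
                "sd_distance": float(np.std(distances, ddof=1)),
            }
        )
    return pd.DataFrame(rows)
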