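"""Readers and writers: FASTA/FASTQ in, profile containers and matrices out.

FASTA is the canonical sequence input (works for both reads and reference
sequences); FASTQ is supported through a conversion path that discards
qualities. Gzip-compressed FASTA/FASTQ is handled transparently by file
extension.

Profiles persist in an HDF5 container: root attribute
``format = "kmer-profile-v1"``, one dataset per profile under the group
``profiles/`` (64-bit unsigned counts, attributes ``k`` and ``label``), and
the base bit-mapping recorded in the root ``encoding`` attribute. Distance
matrices serialize as labelled full-square TSV.
"""

from __future__ import annotations

import gzip
import io as _stdio
from pathlib import Path
from typing import IO, Iterable, Iterator

import h5py
import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .distance import DistanceMatrix
from .profile import Profile, SequenceRecord

FORMAT_VERSION = "kmer-profile-v1"
ENCODING_KEY = "A=00,C=01,G=10,T=11"


def _open_text(source, mode: str = "rt") -> IO[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, mode)
        return open(path, mode)
    return source


def read_fasta(source) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file, path or text handle.

    Multi-line sequences are concatenated; case is preserved for the caller
    to normalize. An empty file yields an empty stream.
    """
    handle = _open_text(source)
    try:
        for title, sequence in SimpleFastaParser(handle):
            yield SequenceRecord(title.split()[0] if title else "", sequence)
    finally:
        if handle is not source:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], sink, width: int = 70) -> int:
    """Write records as FASTA; returns the number written."""
    handle = _open_text(sink, "wt")
    n = 0
    try:
        for record in records:
            handle.write(f">{record.identifier}\n")
            for start in range(0, len(record.sequence), width):
                handle.write(record.sequence[start : start + width] + "\n")
            n += 1
    finally:
        if handle is not sink:
            handle.close()
    return n


def read_fastq(source) -> Iterator[SequenceRecord]:
    """Stream records from 4-line-per-record FASTQ; qualities are dropped."""
    handle = _open_text(source)
    try:
        for title, sequence, _quality in FastqGeneralIterator(handle):
            yield SequenceRecord(title.split()[0] if title else "", sequence)
    finally:
        if handle is not source:
            handle.close()


def fastq_to_fasta(source, sink) -> int:
    """Convert FASTQ to FASTA (identifiers and sequences preserved, qualities
    discarded); returns the number of records converted."""
    return write_fasta(read_fastq(source), sink)


class ProfileContainer:
    """HDF5-backed store for named k-mer profiles.

    Multiple profiles per container are supported (as needed for all-vs-all
    matrix computations). Round-trips of integer-count profiles are exact.
    """

    def __init__(self, path, mode: str = "r"):
        self._h5 = h5py.File(path, mode)
        if "w" in mode or ("a" in mode and "format" not in self._h5.attrs):
            self._h5.attrs["format"] = FORMAT_VERSION
            self._h5.attrs["encoding"] = ENCODING_KEY
            self._h5.require_group("profiles")
        else:
            version = self._h5.attrs.get("format", "")
            if version != FORMAT_VERSION:
                raise ValueError(
                    f"unsupported container format {version!r}; "
                    f"expected {FORMAT_VERSION!r}"
                )

    def __enter__(self) -> "ProfileContainer":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._h5.close()

    def names(self) -> list[str]:
        return sorted(self._h5["profiles"])

    def save(self, p: Profile, name: str | None = None, overwrite: bool = False) -> None:
        name = name or p.label
        if not name:
            raise ValueError("profile needs a name (label empty and none given)")
        group = self._h5.require_group("profiles")
        if name in group:
            if not overwrite:
                raise ValueError(f"profile {name!r} already exists in container")
            del group[name]
        counts = p.counts
        if np.issubdtype(counts.dtype, np.integer) or np.all(counts == np.floor(counts)):
            counts = counts.astype(np.uint64)
        dataset = group.create_dataset(name, data=counts)
        dataset.attrs["k"] = p.k
        dataset.attrs["label"] = p.label

    def load(self, name: str) -> Profile:
        group = self._h5["profiles"]
        if name not in group:
            raise KeyError(f"no profile named {name!r} in container")
        dataset = group[name]
        return Profile(int(dataset.attrs["k"]), dataset[:], str(dataset.attrs["label"]))

    def load_all(self) -> list[Profile]:
        return [self.load(name) for name in self.names()]


def save_profile(path, p: Profile, name: str | None = None, overwrite: bool = False) -> None:
    """Save one profile into a container file (created if missing)."""
    with ProfileContainer(path, "a") as container:
        container.save(p, name=name, overwrite=overwrite)


def load_profile(path, name: str) -> Profile:
    """Load one named profile from a container file."""
    with ProfileContainer(path, "r") as container:
        return container.load(name)


def write_matrix(m: DistanceMatrix, sink) -> None:
    """Write a distance matrix as labelled full-square TSV.

    Line 1: tab-separated labels. Each following line: label + the full row
    of values at 9 significant digits.
    """
    handle = _open_text(sink, "wt")
    try:
        handle.write("\t".join(m.labels) + "\n")
        for label, row in zip(m.labels, m.values):
            handle.write(label + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")
    finally:
        if handle is not sink:
            handle.close()


def read_matrix(source) -> DistanceMatrix:
    """Read a distance matrix written by :func:`write_matrix`."""
    handle = _open_text(source)
    try:
        lines = [line.rstrip("\n") for line in handle if line.strip()]
    finally:
        if handle is not source:
            handle.close()
    if not lines:
        raise ValueError("empty matrix file")
    labels = lines[0].split("\t")
    n = len(labels)
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} rows for {n} labels, got {len(lines) - 1}")
    values = np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        fields = line.split("\t")
        if len(fields) != n + 1:
            raise ValueError(f"row {i} has {len(fields) - 1} values, expected {n}")
        if fields[0] != labels[i]:
            raise ValueError(f"row label {fields[0]!r} != column label {labels[i]!r}")
        values[i] = [float(v) for v in fields[1:]]
    return DistanceMatrix(labels, values)
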