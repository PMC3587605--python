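"""Read containers and FASTQ I/O.

:class:`Reads` is the in-memory unit that flows through the pipeline: a
(possibly ragged) matrix of base codes plus a matching matrix of Phred
qualities. Single reads are exposed as :class:`ReadRecord` for inspection
and testing; bulk operations stay vectorised on the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import PAD, decode, encode


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases, per-base Phred scores."""

    id: str
    sequence: str
    quality: np.ndarray  # integer Phred scores, same length as sequence

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")


class Reads:
    """A batch of reads stored as padded code/quality matrices.

    Attributes
    ----------
    seqs : (n, width) uint8 matrix of base codes, padded with ``PAD``
    quals : (n, width) uint8 matrix of Phred scores, 0 past the read end
    lengths : (n,) int32 read lengths
    ids : optional list of read identifiers
    """

    def __init__(self, seqs: np.ndarray, quals: np.ndarray,
                 lengths: np.ndarray | None = None, ids: list[str] | None = None):
        seqs = np.atleast_2d(np.asarray(seqs, dtype=np.uint8))
        quals = np.atleast_2d(np.asarray(quals, dtype=np.uint8))
        if seqs.shape != quals.shape:
            raise ValueError("seqs and quals shapes differ")
        if lengths is None:
            lengths = np.full(seqs.shape[0], seqs.shape[1], dtype=np.int32)
        self.seqs = seqs
        self.quals = quals
        self.lengths = np.asarray(lengths, dtype=np.int32)
        self.ids = ids

    def __len__(self) -> int:
        return self.seqs.shape[0]

    @property
    def width(self) -> int:
        return self.seqs.shape[1]

    @property
    def fixed_length(self) -> bool:
        return len(self) == 0 or bool((self.lengths == self.lengths[0]).all())

    def subset(self, index: np.ndarray) -> "Reads":
        ids = [self.ids[i] for i in np.atleast_1d(index)] if self.ids else None
        return Reads(self.seqs[index], self.quals[index], self.lengths[index], ids)

    def record(self, i: int) -> ReadRecord:
        n = self.lengths[i]
        rid = self.ids[i] if self.ids else f"read_{i}"
        return ReadRecord(rid, decode(self.seqs[i, :n]), self.quals[i, :n].astype(int))

    def __iter__(self) -> Iterator[ReadRecord]:
        return (self.record(i) for i in range(len(self)))

    @classmethod
    def from_records(cls, records: Iterable[ReadRecord]) -> "Reads":
        records = list(records)
        if not records:
            return cls(np.zeros((0, 0), np.uint8), np.zeros((0, 0), np.uint8))
        width = max(len(r.sequence) for r in records)
        seqs = np.full((len(records), width), PAD, dtype=np.uint8)
        quals = np.zeros((len(records), width), dtype=np.uint8)
        lengths = np.zeros(len(records), dtype=np.int32)
        for i, r in enumerate(records):
            n = len(r.sequence)
            seqs[i, :n] = encode(r.sequence)
            quals[i, :n] = np.asarray(r.quality, dtype=np.uint8)
            lengths[i] = n
        return cls(seqs, quals, lengths, [r.id for r in records])

    @classmethod
    def concat(cls, parts: list["Reads"]) -> "Reads":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls(np.zeros((0, 0), np.uint8), np.zeros((0, 0), np.uint8))
        width = max(p.width for p in parts)
        seqs = np.full((sum(len(p) for p in parts), width), PAD, dtype=np.uint8)
        quals = np.zeros_like(seqs)
        lengths = np.concatenate([p.lengths for p in parts])
        ids: list[str] | None = [] if all(p.ids for p in parts) else None
        row = 0
        for p in parts:
            seqs[row:row + len(p), :p.width] = p.seqs
            quals[row:row + len(p), :p.width] = p.quals
            if ids is not None:
                ids.extend(p.ids)  # type: ignore[arg-type]
            row += len(p)
        return cls(seqs, quals, lengths, ids)


def read_fastq(path) -> Reads:
    """Load a Sanger/Phred+33 FASTQ file."""
    records = []
    with open(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            records.append(ReadRecord(
                rid, seq, np.frombuffer(qual.encode("ascii"), np.uint8) - 33))
    return Reads.from_records(records)


def write_fastq(reads: Reads, path) -> None:
    """Write 4-line FASTQ records with Phred+33 qualities."""
    with open(path, "w") as fh:
        for rec in reads:
            qual = "".join(chr(q + 33) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
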