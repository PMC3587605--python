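"""Demultiplexing, trimming and quality filtering of raw GBS reads.

The rules mirror standard GBS practice on older Illumina chemistry:
exact-match inline barcodes (no mismatches tolerated), a hard trim of every
read to 64 bases in response to 3' quality decay, adapter clipping, and a
whole-read quality rule requiring 95% of bases at Phred >= 15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import PAD, encode
from .reads import Reads
from .simulate import BarcodeSet

TRIM_LENGTH = 64
MIN_QUALITY = 15
MIN_QUALITY_FRACTION = 0.95


@dataclass
class DemuxResult:
    """Per-barcode read streams plus the read-count bookkeeping table."""

    by_barcode: dict[str, Reads]
    counts: pd.DataFrame  # columns: barcode, n_reads (plus an 'unassigned' row)

    @property
    def n_unassigned(self) -> int:
        row = self.counts.loc[self.counts.barcode == "unassigned", "n_reads"]
        return int(row.iloc[0])


def demultiplex(reads: Reads, barcode_set: BarcodeSet) -> DemuxResult:
    """Assign reads to barcodes by exact prefix match and strip the barcode.

    The barcode set must be prefix-free (enforced by BarcodeSet), so at most
    one barcode can match a given read; reads matching none are counted as
    unassigned. Cut-site remnant bases after the barcode are genomic and are
    retained.
    """
    n = len(reads)
    assignment = np.full(n, -1, dtype=np.int64)
    by_length: dict[int, dict[int, int]] = {}
    for bi, seq in enumerate(barcode_set.sequences):
        codes = encode(seq).astype(np.int64)
        key = int(codes @ (4 ** np.arange(codes.size, dtype=np.int64)))
        by_length.setdefault(codes.size, {})[key] = bi
    for length, table in by_length.items():
        if reads.width < length:
            continue
        ok = reads.lengths >= length
        prefix = reads.seqs[:, :length].astype(np.int64)
        # PAD (4) codes make the key fall outside any barcode's key space
        keys = prefix @ (4 ** np.arange(length, dtype=np.int64))
        barcode_ids = np.array(sorted(table))
        idx = np.searchsorted(barcode_ids, keys)
        idx[idx == barcode_ids.size] = 0
        hit = ok & (barcode_ids[idx] == keys)
        for key in barcode_ids[np.unique(idx[hit])]:
            bi = table[int(key)]
            rows = np.flatnonzero(hit & (barcode_ids[idx] == key))
            assignment[rows] = bi

    by_barcode: dict[str, Reads] = {}
    records = []
    for bi, seq in enumerate(barcode_set.sequences):
        rows = np.flatnonzero(assignment == bi)
        blen = len(seq)
        sub = reads.subset(rows)
        # strip the barcode; re-pad on the right
        width = sub.width
        seqs = np.full((rows.size, width), PAD, dtype=np.uint8)
        quals = np.zeros((rows.size, width), dtype=np.uint8)
        seqs[:, :width - blen] = sub.seqs[:, blen:]
        quals[:, :width - blen] = sub.quals[:, blen:]
        by_barcode[seq] = Reads(seqs, quals, sub.lengths - blen, sub.ids)
        records.append({"barcode": seq, "n_reads": rows.size})
    records.append({"barcode": "unassigned",
                    "n_reads": int((assignment == -1).sum())})
    counts = pd.DataFrame(records)
    assert counts.n_reads.sum() == n, "demultiplex count conservation violated"
    return DemuxResult(by_barcode, counts)


def _find_adapter(seqs: np.ndarray, adapter: str, width: int) -> np.ndarray:
    """Leftmost position of an adapter occurrence within the first ``width``
    bases of each read (a prefix of the adapter suffices at the read end);
    ``width`` where absent."""
    ad = encode(adapter)
    n = seqs.shape[0]
    found = np.full(n, width, dtype=np.int64)
    for p in range(width - 1, -1, -1):
        m = min(ad.size, width - p)
        match = (seqs[:, p:p + m] == ad[:m]).all(axis=1)
        found[match] = p
    return found


def preprocess_reads(reads: Reads, trim_to: int = TRIM_LENGTH,
                     min_q: int = MIN_QUALITY,
                     min_frac: float = MIN_QUALITY_FRACTION,
                     adapter: str | None = None) -> Reads:
    """Trim, adapter-clip and quality-filter demultiplexed reads.

    Order of operations: (1) trim every read to ``trim_to`` bases; (2) clip
    at the leftmost adapter occurrence; (3) drop reads now shorter than
    ``trim_to``; (4) drop reads where the fraction of bases with
    Phred >= ``min_q`` falls below ``min_frac``. Survivors are all exactly
    ``trim_to`` long, so the operation is idempotent.
    """
    if trim_to <= 0:
        raise ValueError("trim_to must be positive")
    keep = reads.lengths >= trim_to
    if adapter:
        has_room = reads.seqs.shape[1] >= trim_to
        if len(reads) and has_room:
            adapter_at = _find_adapter(reads.seqs[:, :trim_to], adapter, trim_to)
            keep &= adapter_at >= trim_to
    if not len(reads):
        return Reads(np.zeros((0, trim_to), np.uint8),
                     np.zeros((0, trim_to), np.uint8))
    q_ok = (reads.quals[:, :trim_to] >= min_q).sum(axis=1) >= math.ceil(
        min_frac * trim_to)
    keep &= q_ok
    rows = np.flatnonzero(keep)
    ids = [reads.ids[i] for i in rows] if reads.ids else None
    return Reads(reads.seqs[rows, :trim_to].copy(),
                 reads.quals[rows, :trim_to].copy(), ids=ids)


def read_count_stats(counts: pd.DataFrame, trim_lowest: int = 0) -> dict:
    """Mean, SD (n-1 denominator) and coefficient of variation of per-sample
    read counts; optionally recomputed after removing the ``trim_lowest``
    lowest-count samples (outlier handling for failed samples)."""
    values = counts.loc[counts.barcode != "unassigned", "n_reads"] \
        if "barcode" in counts else counts["n_reads"]
    values = np.sort(np.asarray(values, dtype=float))
    if values.size < 2:
        raise ValueError("need at least two samples")
    if values.mean() == 0:
        raise ValueError("zero mean read count")
    out = {"mean": values.mean(), "sd": values.std(ddof=1),
           "cv": values.std(ddof=1) / values.mean()}
    if trim_lowest:
        t = values[trim_lowest:]
        out.update(trimmed_mean=t.mean(), trimmed_sd=t.std(ddof=1),
                   trimmed_cv=t.std(ddof=1) / t.mean())
    return out
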