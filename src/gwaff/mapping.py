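"""Map reads back to consensus loci and pile up base counts.

Mapping is ungapped, end-to-end Hamming matching of equal-length reads
against locus consensuses, keeping a read only if exactly one locus lies
within the mismatch bound (the classic bowtie ``-v 2 -m 1`` contract).
Both orientations are searched; the two orientations of one locus count as
a single candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, segment_bounds, segment_keys, unique_rows
from .assemble import LocusSet
from .reads import Reads

MAX_MISMATCH = 2

UNMAPPED = -1
AMBIGUOUS = -2


class LocusIndex:
    """Exact-segment (pigeonhole) index over locus consensuses.

    With mismatch bound v, a read matching a locus within v mismatches must
    agree exactly on at least one of v+1 segments, so looking up each read
    segment in exact-match hash buckets (forward and reverse-complement)
    retrieves a candidate superset; candidates are then verified by full
    Hamming distance. Lookup is therefore equivalent to a linear scan.
    """

    def __init__(self, loci: LocusSet, max_mismatch: int = MAX_MISMATCH):
        self.loci = loci
        self.max_mismatch = max_mismatch
        self.consensus = loci.consensus
        self.bounds = segment_bounds(loci.width, max_mismatch + 1)
        keys = segment_keys(loci.consensus, self.bounds)
        self._tables: list[dict[int, np.ndarray]] = []
        for s in range(len(self.bounds)):
            table: dict[int, list[int]] = {}
            for li, k in enumerate(keys[:, s]):
                table.setdefault(int(k), []).append(li)
            self._tables.append({k: np.array(v, dtype=np.int64)
                                 for k, v in table.items()})

    def candidates(self, fwd_keys: np.ndarray, rc_keys: np.ndarray) -> np.ndarray:
        """Candidate locus ids for one read given its segment keys in both
        orientations. A forward hit means read ~ consensus, so the read's
        own keys are probed; a reverse hit means rc(read) ~ consensus, so
        the reverse-complemented read's keys are probed against the same
        forward tables."""
        hits: list[np.ndarray] = []
        for s in range(len(self.bounds)):
            for key in (int(fwd_keys[s]), int(rc_keys[s])):
                found = self._tables[s].get(key)
                if found is not None:
                    hits.append(found)
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))


@dataclass
class MapResult:
    """Per-read mapping outcome. ``locus`` holds a locus id, or UNMAPPED /
    AMBIGUOUS; ``reverse`` flags hits in reverse-complement orientation."""

    locus: np.ndarray
    reverse: np.ndarray

    @property
    def n_mapped(self) -> int:
        return int((self.locus >= 0).sum())


def map_reads(reads: Reads, index: LocusIndex,
              max_mismatch: int | None = None,
              unique_only: bool = True) -> MapResult:
    """Map each read to loci with bounded mismatches (-v) and, by default,
    discard multi-locus hits (-m 1). Per locus the better of the two
    orientations is used before counting candidates."""
    if max_mismatch is None:
        max_mismatch = index.max_mismatch
    if len(reads) and reads.width != index.loci.width:
        raise ValueError("read length differs from locus length")
    n = len(reads)
    locus = np.full(n, UNMAPPED, dtype=np.int64)
    reverse = np.zeros(n, dtype=bool)
    if n == 0 or len(index.loci) == 0:
        return MapResult(locus, reverse)

    uniq, _, inverse = unique_rows(reads.seqs)
    rc = revcomp(uniq).copy()
    fwd_keys = segment_keys(uniq, index.bounds)
    rc_keys = segment_keys(rc, index.bounds)
    u_locus = np.full(uniq.shape[0], UNMAPPED, dtype=np.int64)
    u_rev = np.zeros(uniq.shape[0], dtype=bool)
    cons = index.consensus
    for i in range(uniq.shape[0]):
        cand = index.candidates(fwd_keys[i], rc_keys[i])
        if cand.size == 0:
            continue
        d_fwd = (cons[cand] != uniq[i]).sum(axis=1)
        d_rc = (cons[cand] != rc[i]).sum(axis=1)
        d = np.minimum(d_fwd, d_rc)
        ok = d <= max_mismatch
        n_ok = int(ok.sum())
        if n_ok == 1 or (n_ok > 1 and not unique_only):
            best = cand[ok][np.argmin(d[ok])] if n_ok > 1 else cand[ok][0]
            pos = int(np.flatnonzero(cand == best)[0])
            u_locus[i] = best
            u_rev[i] = d_rc[pos] < d_fwd[pos]
        elif n_ok > 1:
            u_locus[i] = AMBIGUOUS
    locus = u_locus[inverse]
    reverse = u_rev[inverse]
    return MapResult(locus, reverse)


def build_pileup(reads: Reads, result: MapResult, loci: LocusSet) -> np.ndarray:
    """Per-locus base counts: an (n_loci, width, 4) array where entry
    [l, o, b] counts reads mapped to locus l showing base b at offset o.
    Reverse-orientation reads contribute complemented bases at mirrored
    offsets (their coordinates are lifted into the locus frame)."""
    width = loci.width
    pileup = np.zeros((len(loci), width, 4), dtype=np.int64)
    mapped = np.flatnonzero(result.locus >= 0)
    if mapped.size == 0:
        return pileup
    for orient in (False, True):
        rows = mapped[result.reverse[mapped] == orient]
        if rows.size == 0:
            continue
        seqs = reads.seqs[rows]
        if orient:
            seqs = revcomp(seqs)
        flat = (result.locus[rows, None] * (width * 4)
                + np.arange(width)[None, :] * 4 + seqs)
        pileup += np.bincount(flat.ravel(),
                              minlength=pileup.size).reshape(pileup.shape)
    return pileup


def pileup_to_frame(pileup: np.ndarray):
    """Long-format pileup table (locus_id, offset, A, C, G, T, depth)."""
    import pandas as pd
    n_loci, width, _ = pileup.shape
    idx = pd.MultiIndex.from_product([range(n_loci), range(width)],
                                     names=["locus_id", "offset"])
    df = pd.DataFrame(pileup.reshape(-1, 4), index=idx,
                      columns=list("ACGT")).reset_index()
    df["depth"] = df[list("ACGT")].sum(axis=1)
    return df
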