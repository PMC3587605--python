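"""Low-level nucleotide sequence utilities.

Sequences are held as numpy ``uint8`` code arrays with A=0, C=1, G=2, T=3.
A padding sentinel (:data:`PAD`) marks positions past the end of a read in
ragged read matrices; it never compares equal to a real base.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PAD = np.uint8(4)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# IUPAC degenerate nucleotide codes -> the set of base codes they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        bad = seq[int(np.argmax(codes > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a 1-D code array back to an ACGT string (PAD is dropped)."""
    codes = np.asarray(codes)
    codes = codes[codes != PAD]
    return "".join(BASES[c] for c in codes)


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis (complement of code c is 3-c)."""
    return (3 - np.asarray(codes))[..., ::-1]


def revcomp_str(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def iupac_allowed(pattern: str) -> list[np.ndarray]:
    """Per-position arrays of base codes matched by an IUPAC pattern."""
    out = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"unknown IUPAC code {ch!r}")
        out.append(np.array([BASES.index(b) for b in IUPAC[ch]], dtype=np.uint8))
    return out


def iupac_expand(pattern: str) -> list[str]:
    """All concrete ACGT strings matched by an IUPAC pattern."""
    seqs = [""]
    for ch in pattern.upper():
        seqs = [s + b for s in seqs for b in IUPAC[ch]]
    return seqs


def hamming_matrix(a: np.ndarray, b: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Pairwise Hamming distances between the rows of two equal-width code
    matrices, computed in row chunks of ``a`` to bound peak memory."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("sequence lengths differ")
    out = np.empty((a.shape[0], b.shape[0]), dtype=np.int32)
    for lo in range(0, a.shape[0], chunk):
        hi = min(lo + chunk, a.shape[0])
        out[lo:hi] = (a[lo:hi, None, :] != b[None, :, :]).sum(axis=2)
    return out


def segment_bounds(length: int, n_segments: int) -> list[tuple[int, int]]:
    """Split ``[0, length)`` into ``n_segments`` near-equal half-open pieces."""
    edges = np.linspace(0, length, n_segments + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_segments)]


def unique_rows(seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lexicographically sorted unique rows of a code matrix, with counts
    and the inverse mapping. Rows are packed into a few int64 keys (2 bits
    per base, 31 bases per key) and sorted on those, which is much faster
    than generic row-wise uniquing for long read matrices."""
    seqs = np.atleast_2d(seqs)
    n, width = seqs.shape
    if n == 0:
        return seqs.copy(), np.zeros(0, np.int64), np.zeros(0, np.int64)
    bounds = [(lo, min(lo + 31, width)) for lo in range(0, width, 31)]
    keys = np.empty((n, len(bounds)), dtype=np.int64)
    for j, (lo, hi) in enumerate(bounds):
        powers = 4 ** np.arange(hi - lo - 1, -1, -1, dtype=np.int64)
        keys[:, j] = seqs[:, lo:hi].astype(np.int64) @ powers
    order = np.lexsort(keys.T[::-1])
    sorted_keys = keys[order]
    first = np.r_[True, (np.diff(sorted_keys, axis=0) != 0).any(axis=1)]
    group = np.cumsum(first) - 1
    inverse = np.empty(n, dtype=np.int64)
    inverse[order] = group
    return seqs[order[first]].copy(), np.bincount(group), inverse


def segment_keys(seqs: np.ndarray, bounds: list[tuple[int, int]]) -> np.ndarray:
    """Integer keys (one column per segment) identifying each row's exact
    segment sequences; base-4 polynomial encoding, fits int64 for <=31 bases."""
    seqs = np.atleast_2d(seqs)
    cols = []
    for lo, hi in bounds:
        powers = (4 ** np.arange(hi - lo, dtype=np.int64))
        cols.append(seqs[:, lo:hi].astype(np.int64) @ powers)
    return np.stack(cols, axis=1)
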