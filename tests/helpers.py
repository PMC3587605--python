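"""Shared test utilities: tiny constructors and independent brute-force
oracles (all-pairs clustering, linear-scan mapping) that the fast
implementations are checked against."""

from __future__ import annotations

from collections import Counter

import numpy as np

from gwaff._seq import BASES, decode, encode
from gwaff.reads import Reads


def reads_from_strings(seqs: list[str], quality: int | list = 30,
                       ids: list[str] | None = None) -> Reads:
    records = []
    from gwaff.reads import ReadRecord
    for i, s in enumerate(seqs):
        q = quality[i] if isinstance(quality, list) else quality
        qual = np.full(len(s), q, dtype=np.uint8) if np.isscalar(q) \
            else np.asarray(q, dtype=np.uint8)
        rid = ids[i] if ids else f"r{i}"
        records.append(ReadRecord(rid, s, qual))
    return Reads.from_records(records)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def revcomp_str(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(s))


def random_separated_loci(rng: np.random.Generator, n: int, length: int = 64,
                          min_dist: int = 9) -> list[str]:
    """Random sequences, pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    while len(out) < n:
        cand = decode(rng.integers(0, 4, length).astype(np.uint8))
        if all(hamming(cand, o) >= min_dist for o in out):
            out.append(cand)
    return out


def mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Exactly k substitutions at distinct random positions."""
    codes = encode(seq).copy()
    pos = rng.choice(len(seq), k, replace=False)
    codes[pos] = (codes[pos] + rng.integers(1, 4, k)) % 4
    return decode(codes)


# ---------------------------------------------------------------------------
# all-pairs assembly oracle (mirrors the stated stack-assembly semantics)


def oracle_assemble(seqs: list[str], min_stack_depth: int = 3,
                    max_stack_dist: int = 2, max_secondary_dist: int = 4):
    """Exhaustive reference assembly. Returns (sorted list of
    (consensus, total_depth), n_dropped)."""
    counts = Counter(seqs)
    primary = {s: c for s, c in counts.items() if c >= min_stack_depth}
    secondary = {s: c for s, c in counts.items() if c < min_stack_depth}
    stacks = sorted(primary)
    # connected components over Hamming <= max_stack_dist
    parent = list(range(len(stacks)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(stacks)):
        for j in range(i + 1, len(stacks)):
            if hamming(stacks[i], stacks[j]) <= max_stack_dist:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(stacks)):
        groups.setdefault(find(i), []).append(i)

    loci = []
    for members in groups.values():
        width = len(stacks[members[0]])
        consensus = []
        for pos in range(width):
            tally = {b: 0 for b in BASES}
            for m in members:
                tally[stacks[m][pos]] += primary[stacks[m]]
            best = max(tally.values())
            consensus.append(min(b for b in BASES if tally[b] == best))
        loci.append(["".join(consensus),
                     sum(primary[stacks[m]] for m in members)])

    dropped = 0
    for s, c in secondary.items():
        dists = [hamming(s, cons) for cons, _ in loci]
        if not dists:
            dropped += c
            continue
        dmin = min(dists)
        if dmin > max_secondary_dist or dists.count(dmin) > 1:
            dropped += c
        else:
            loci[dists.index(dmin)][1] += c
    return sorted((cons, depth) for cons, depth in loci), dropped


# ---------------------------------------------------------------------------
# linear-scan mapping oracle (-v max_mismatch, -m 1 semantics)


def oracle_map(read: str, loci: list[str], max_mismatch: int = 2):
    """Returns (outcome, reverse) where outcome is a locus index, 'unmapped'
    or 'ambiguous'; per locus the better orientation is used."""
    rc = revcomp_str(read)
    hits = []
    for i, cons in enumerate(loci):
        d_fwd = hamming(read, cons)
        d_rc = hamming(rc, cons)
        d = min(d_fwd, d_rc)
        if d <= max_mismatch:
            hits.append((i, d, d_rc < d_fwd))
    if not hits:
        return "unmapped", False
    if len(hits) > 1:
        return "ambiguous", False
    i, _, rev = hits[0]
    return i, rev
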