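"""Synthetic pooled genotyping-by-sequencing (GBS) data with known truth.

The generator emulates the statistical structure a pooled-GBS analysis
rests on: a genome cut by a restriction enzyme, size selection of
cut-bounded fragments, polycross populations carrying many founder
haplotypes (so each population is characterised by per-site pool allele
frequencies rather than genotypes), non-uniform locus amplification
favouring short fragments, inline variable-length barcodes, and
substitution sequencing error on fixed-length single-end reads.

Every stochastic operation takes an explicit integer seed and is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, decode, iupac_allowed, iupac_expand, revcomp, revcomp_str
from .reads import Reads


# ---------------------------------------------------------------------------
# restriction enzymes and digestion


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition pattern and top-strand cut
    offset. The pattern must be palindromic under IUPAC expansion (type II
    enzymes cut double-stranded sites)."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise ValueError("recognition pattern shorter than 4 bases")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition pattern")
        expanded = set(iupac_expand(self.recognition))
        if {revcomp_str(s) for s in expanded} != expanded:
            raise ValueError(
                f"{self.recognition} is not reverse-complement closed")

    @property
    def site_probability(self) -> float:
        """Probability a random position starts a recognition site."""
        return len(iupac_expand(self.recognition)) / 4 ** len(self.recognition)


#: ApeKI: frequent cutter, 5 bp site with a 1 bp wobble (W = A/T), cuts G^CWGC.
APEKI = Enzyme("ApeKI", "GCWGC", 1)
#: PstI: rare cutter, 6 bp site, cuts CTGCA^G.
PSTI = Enzyme("PstI", "CTGCAG", 5)

ENZYMES = {e.name: e for e in (APEKI, PSTI)}


@dataclass(frozen=True)
class SyntheticGenome:
    sequence: str
    gc_content: float
    seed: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: half-open genome interval plus flags saying
    whether each boundary is a cut site (chromosome ends are not)."""

    start: int
    end: int
    left_cut: bool
    right_cut: bool
    sequence: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("empty fragment")
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval and sequence lengths differ")

    def __len__(self) -> int:
        return self.end - self.start


def generate_genome(length: int, gc: float = 0.5, seed: int = 0) -> SyntheticGenome:
    """I.i.d. random genome with the requested GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    # code order A,C,G,T
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return SyntheticGenome(decode(codes), gc, seed)


def find_cut_positions(codes: np.ndarray, enzyme: Enzyme) -> np.ndarray:
    """Top-strand scan for recognition sites; returns cut coordinates."""
    m = len(enzyme.recognition)
    n = codes.size - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j, allowed in enumerate(iupac_allowed(enzyme.recognition)):
        valid &= np.isin(codes[j:j + n], allowed)
    cuts = np.flatnonzero(valid) + enzyme.cut_offset
    cuts = cuts[(cuts > 0) & (cuts < codes.size)]
    return np.unique(cuts)


def digest(sequence: str | SyntheticGenome, enzyme: Enzyme) -> list[Fragment]:
    """Complete in-silico digestion: fragments are the intervals between
    consecutive cut positions plus the two chromosome-end intervals."""
    seq = sequence.sequence if isinstance(sequence, SyntheticGenome) else sequence
    if not seq:
        raise ValueError("empty sequence")
    codes = encode(seq)
    cuts = find_cut_positions(codes, enzyme)
    bounds = np.concatenate(([0], cuts, [len(seq)]))
    frags = []
    for i in range(len(bounds) - 1):
        s, e = int(bounds[i]), int(bounds[i + 1])
        frags.append(Fragment(s, e, left_cut=i > 0,
                              right_cut=i < len(bounds) - 2,
                              sequence=seq[s:e]))
    return frags


def select_fragments(fragments: list[Fragment], min_len: int = 100,
                     max_len: int = 1000) -> list[Fragment]:
    """Sequenceable fragments: cut sites at both ends (adapters ligate to cut
    overhangs only) and length within the size-selection window, inclusive."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    return [f for f in fragments
            if f.left_cut and f.right_cut and min_len <= len(f) <= max_len]


# ---------------------------------------------------------------------------
# populations


@dataclass
class PopulationModel:
    """A polycross population as a pool of founder haplotypes.

    ``true_af[j]`` is the pool frequency of the alternate allele at variant
    site ``j`` and always equals the column mean of ``founder_haplotypes``
    (0/1 alt-dose indicators, one row per founder haplotype).
    """

    name: str
    n_founders: int
    variant_sites: np.ndarray      # structured: pos, ref, alt (codes)
    founder_haplotypes: np.ndarray  # (n_founders, n_sites) uint8
    true_af: np.ndarray = field(init=False)

    def __post_init__(self):
        self.true_af = self.founder_haplotypes.mean(axis=0)

    @property
    def n_sites(self) -> int:
        return self.variant_sites.shape[0]


_SITE_DTYPE = np.dtype([("pos", np.int64), ("ref", np.uint8), ("alt", np.uint8)])


def _place_sites(genome: SyntheticGenome, snp_density: float,
                 rng: np.random.Generator) -> np.ndarray:
    codes = encode(genome.sequence)
    pos = np.flatnonzero(rng.random(genome.length) < snp_density)
    sites = np.empty(pos.size, dtype=_SITE_DTYPE)
    sites["pos"] = pos
    sites["ref"] = codes[pos]
    sites["alt"] = (codes[pos] + rng.integers(1, 4, pos.size)) % 4
    return sites


def _haplotypes_from_af(target_af: np.ndarray, n_founders: int,
                        rng: np.random.Generator,
                        truncate: bool) -> np.ndarray:
    """Realize target frequencies as the nearest achievable founder-count
    fraction k/n_founders and scatter the k alt alleles over founders."""
    k = np.rint(target_af * n_founders).astype(int)
    if truncate:
        k = np.clip(k, 1, n_founders - 1)
    else:
        k = np.clip(k, 0, n_founders)
    hap = np.zeros((n_founders, target_af.size), dtype=np.uint8)
    for j, kj in enumerate(k):
        hap[rng.permutation(n_founders)[:kj], j] = 1
    return hap


def make_population(genome: SyntheticGenome, n_founders: int = 24,
                    snp_density: float = 0.01, seed: int = 0,
                    beta_shape: tuple[float, float] = (0.8, 0.8),
                    name: str = "pop") -> PopulationModel:
    """Single polycross population: variant sites placed i.i.d. along the
    genome, pool frequencies drawn from a Beta truncated away from 0/1 and
    quantised to founder-count fractions."""
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if snp_density <= 0:
        raise ValueError("snp_density must be positive")
    rng = np.random.default_rng(seed)
    sites = _place_sites(genome, snp_density, rng)
    target = rng.beta(*beta_shape, size=sites.size)
    hap = _haplotypes_from_af(target, n_founders, rng, truncate=True)
    return PopulationModel(name, n_founders, sites, hap)


def balding_nichols_af(n_pops: int, n_sites: int, fst: float,
                       rng: np.random.Generator | int,
                       n_founders: int = 24,
                       beta_shape: tuple[float, float] = (0.8, 0.8),
                       ) -> np.ndarray:
    """(n_pops, n_sites) matrix of population allele frequencies under the
    Balding–Nichols model: each site has an ancestral frequency
    q ~ Beta(*beta_shape*); population k draws its frequency from
    Beta(q(1-F)/F, (1-q)(1-F)/F) with F the Fst divergence parameter, then
    quantises to the nearest founder-count fraction k/n_founders. A
    population may be fixed at a site; sites stay variable overall."""
    if not 0 < fst < 1:
        raise ValueError("fst must lie in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    q = rng.beta(*beta_shape, size=n_sites)
    scale = (1 - fst) / fst
    p = rng.beta(np.maximum(q[None, :] * scale, 1e-9),
                 np.maximum((1 - q[None, :]) * scale, 1e-9),
                 size=(n_pops, n_sites))
    return np.clip(np.rint(p * n_founders), 0, n_founders) / n_founders


def make_populations(genome: SyntheticGenome, n_pops: int = 8,
                     n_founders: int = 24, snp_density: float = 0.01,
                     fst: float = 0.05, seed: int = 0,
                     beta_shape: tuple[float, float] = (0.8, 0.8),
                     ) -> list[PopulationModel]:
    """Several populations segregating at a shared set of variant sites,
    with Balding–Nichols between-population divergence
    (see :func:`balding_nichols_af`)."""
    rng = np.random.default_rng(seed)
    sites = _place_sites(genome, snp_density, rng)
    af = balding_nichols_af(n_pops, sites.size, fst, rng, n_founders,
                            beta_shape)
    pops = []
    for k in range(n_pops):
        hap = _haplotypes_from_af(af[k], n_founders, rng, truncate=False)
        pops.append(PopulationModel(f"pop{k}", n_founders, sites, hap))
    return pops


def resample_pool(pop: PopulationModel, n_haplotypes: int, seed: int,
                  name: str | None = None) -> PopulationModel:
    """Finite seedling pool: draw ``n_haplotypes`` founder haplotypes with
    replacement, giving a sampling replicate whose pool frequencies deviate
    from the variety's by the seedling-draw noise."""
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, pop.n_founders, size=n_haplotypes)
    return PopulationModel(name or f"{pop.name}_resampled", n_haplotypes,
                           pop.variant_sites, pop.founder_haplotypes[rows])


# ---------------------------------------------------------------------------
# barcodes


@dataclass
class BarcodeSet:
    """Inline barcodes with relative amplification efficiencies. Variable
    lengths stagger the cut-site remnant across sequencing cycles; the set
    must be prefix-free so exact-prefix demultiplexing is unambiguous."""

    barcodes: list[tuple[str, float]]

    def __post_init__(self):
        seqs = self.sequences
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate barcode sequences")
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                if i != j and b.startswith(a):
                    raise ValueError(f"barcode {a} is a prefix of {b}")
        if any(w <= 0 for _, w in self.barcodes):
            raise ValueError("barcode efficiencies must be positive")

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.barcodes]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.barcodes])

    def __len__(self) -> int:
        return len(self.barcodes)


def make_barcode_set(n: int, lengths: tuple[int, int] = (4, 8), seed: int = 0,
                     efficiency_sigma: float = 0.0) -> BarcodeSet:
    """Random distinct, prefix-free barcodes with lengths cycling over
    ``lengths`` (inclusive range). ``efficiency_sigma`` > 0 draws lognormal
    per-barcode efficiencies emulating uneven sample representation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = lengths
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    cycle = list(range(lo, hi + 1))
    tries = 0
    while len(chosen) < n:
        if tries > 10000 * n:
            raise ValueError("cannot build a prefix-free set of that size")
        tries += 1
        length = cycle[len(chosen) % len(cycle)]
        cand = decode(rng.integers(0, 4, length).astype(np.uint8))
        if any(cand.startswith(b) or b.startswith(cand) or cand == b
               for b in chosen):
            continue
        chosen.append(cand)
    if efficiency_sigma > 0:
        eff = np.exp(rng.normal(0.0, efficiency_sigma, n))
    else:
        eff = np.ones(n)
    return BarcodeSet(list(zip(chosen, eff)))


# ---------------------------------------------------------------------------
# read generation


@dataclass
class SimConfig:
    """Sequencing/library parameters.

    length_bias_scale is the exponential decay length (bases) of the
    short-fragment amplification advantage; locus_lognormal_sigma adds
    per-locus lognormal efficiency noise on top. Together they produce the
    strongly non-uniform locus coverage pooled GBS exhibits.
    """

    enzyme: Enzyme = PSTI
    read_length: int = 101
    substitution_error_rate: float = 0.002
    length_bias_scale: float = 300.0
    locus_lognormal_sigma: float = 1.0
    min_fragment: int = 100
    max_fragment: int = 1000
    base_quality: int = 30
    low_quality_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for r in (self.substitution_error_rate, self.low_quality_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


def assign_fragment_weights(fragments: list[Fragment], cfg: SimConfig,
                            seed: int = 0) -> np.ndarray:
    """Per-fragment sampling weights: lognormal locus efficiency times an
    exponential short-fragment bias, normalised to sum to one."""
    if not fragments:
        raise ValueError("no fragments to weight")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(f) for f in fragments], dtype=float)
    log_w = -lengths / cfg.length_bias_scale
    if cfg.locus_lognormal_sigma > 0:
        log_w = log_w + rng.normal(0.0, cfg.locus_lognormal_sigma, len(fragments))
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def _fragment_templates(fragments: list[Fragment], pop: PopulationModel,
                        g: int) -> dict[tuple[int, int], tuple[np.ndarray, list]]:
    """Per (fragment, end) read template of length g and the variant sites it
    covers as (offset, alt_code, site_index) in template orientation."""
    pos = pop.variant_sites["pos"]
    alt = pop.variant_sites["alt"]
    out = {}
    for fi, f in enumerate(fragments):
        codes = encode(f.sequence)
        cover = np.flatnonzero((pos >= f.start) & (pos < f.end))
        # end 0: read runs forward from the left cut remnant
        sites0 = [(int(pos[j] - f.start), int(alt[j]), int(j))
                  for j in cover if pos[j] - f.start < g]
        out[(fi, 0)] = (codes[:g].copy(), sites0)
        # end 1: reverse-complement strand from the right cut remnant
        rc = revcomp(codes)
        sites1 = [(int(f.end - 1 - pos[j]), int(3 - alt[j]), int(j))
                  for j in cover if f.end - 1 - pos[j] < g]
        out[(fi, 1)] = (rc[:g].copy(), sites1)
    return out


def generate_reads(pop: PopulationModel, fragments: list[Fragment],
                   weights: np.ndarray, barcode: str, n_reads: int,
                   cfg: SimConfig, seed: int = 0) -> Reads:
    """Simulate barcoded single-end reads from one pooled sample.

    Per read: a fragment is drawn by weight; either end is sequenced with
    equal probability (the far end reads the reverse-complement strand); at
    each variant site covered the alternate allele is emitted independently
    with probability ``true_af`` (infinite-template pool sampling); the read
    is barcode + genomic bases truncated to ``read_length``; substitution
    errors hit post-barcode bases i.i.d.; qualities are constant
    ``base_quality`` except for a ``low_quality_fraction`` of reads whose
    per-base scores are uniform on [2, 14] (these fail the standard filter).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    bc = encode(barcode)
    g = cfg.read_length - bc.size
    if n_reads == 0:
        return Reads(np.zeros((0, cfg.read_length), np.uint8),
                     np.zeros((0, cfg.read_length), np.uint8))
    if fragments and g > min(len(f) for f in fragments):
        raise ValueError("read extends past the shortest fragment; "
                         "check read_length vs min_fragment")
    rng = np.random.default_rng(seed)
    frag_idx = rng.choice(len(fragments), size=n_reads, p=weights)
    end = rng.integers(0, 2, size=n_reads)
    templates = _fragment_templates(fragments, pop, g)

    seqs = np.empty((n_reads, cfg.read_length), dtype=np.uint8)
    seqs[:, :bc.size] = bc
    key = frag_idx * 2 + end
    order = np.argsort(key, kind="stable")
    boundaries = np.flatnonzero(np.diff(key[order])) + 1
    for rows in np.split(order, boundaries):
        fi, e = divmod(int(key[rows[0]]), 2)
        template, sites = templates[(fi, e)]
        block = np.tile(template, (rows.size, 1))
        for off, alt_code, j in sites:
            hit = rng.random(rows.size) < pop.true_af[j]
            block[hit, off] = alt_code
        if cfg.substitution_error_rate > 0:
            err = rng.random(block.shape) < cfg.substitution_error_rate
            n_err = int(err.sum())
            if n_err:
                block[err] = (block[err] + rng.integers(1, 4, n_err)) % 4
        seqs[rows, bc.size:] = block

    quals = np.full((n_reads, cfg.read_length), cfg.base_quality, dtype=np.uint8)
    if cfg.low_quality_fraction > 0:
        lowq = np.flatnonzero(rng.random(n_reads) < cfg.low_quality_fraction)
        quals[lowq] = rng.integers(2, 15, size=(lowq.size, cfg.read_length))
    return Reads(seqs, quals)


# ---------------------------------------------------------------------------
# ground truth bookkeeping for recovery experiments


@dataclass
class TruthLocus:
    """The genomic truth behind one assembled locus: which fragment end it
    came from, its error-free template, and the variant sites it carries in
    template orientation (offset -> ref code, alt code, site index)."""

    fragment_index: int
    end: int
    template: np.ndarray
    sites: dict[int, tuple[int, int, int]]


def build_truth_loci(fragments: list[Fragment], pops: list[PopulationModel],
                     locus_len: int = 64) -> list[TruthLocus]:
    """Enumerate the expected loci (both ends of every sequenceable fragment)
    with their variant content. All populations must share variant sites."""
    pop = pops[0]
    templates = _fragment_templates(fragments, pop, locus_len)
    ref = pop.variant_sites["ref"]
    out = []
    for (fi, e), (template, sites) in sorted(templates.items()):
        site_map = {}
        for off, alt_code, j in sites:
            ref_code = int(ref[j]) if e == 0 else int(3 - ref[j])
            site_map[off] = (ref_code, alt_code, j)
        out.append(TruthLocus(fi, e, template, site_map))
    return out


def match_loci_to_truth(consensus: np.ndarray, truth: list[TruthLocus],
                        max_dist: int = 2) -> np.ndarray:
    """Map each assembled consensus row to the truth locus it reproduces:
    exact template match first, else the unique truth template within
    ``max_dist`` mismatches; -1 where neither exists."""
    from ._seq import hamming_matrix
    lookup = {t.template.tobytes(): i for i, t in enumerate(truth)}
    result = np.full(consensus.shape[0], -1, dtype=np.int64)
    misses = []
    for i in range(consensus.shape[0]):
        hit = lookup.get(consensus[i].tobytes())
        if hit is None:
            misses.append(i)
        else:
            result[i] = hit
    if misses:
        tmpl = np.stack([t.template for t in truth])
        d = hamming_matrix(consensus[misses], tmpl)
        dmin = d.min(axis=1)
        unique = (d == dmin[:, None]).sum(axis=1) == 1
        ok = (dmin <= max_dist) & unique
        result[np.array(misses)[ok]] = d.argmin(axis=1)[ok]
    return result
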