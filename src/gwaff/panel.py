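"""Reference SNP panel from an equal-read pool of all populations.

Pooling the same number of quality-filtered reads from every population
gives each population equal weight, so the pooled minor-allele frequency
estimates the mean frequency across populations. A site enters the panel
if it is cleanly bi-allelic (top two bases each supported by at least
``min_allele_reads`` reads, any third base below that support) and the
pooled MAF clears the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import BASES
from .reads import Reads

MIN_ALLELE_READS = 5


@dataclass
class SNPPanel:
    """Bi-allelic reference SNP sites discovered from the pooled pileup.

    ``sites`` columns: locus_id, offset, ref (pool-major base), alt
    (pool-minor base), pool_maf, pool_depth; sorted by (locus_id, offset).
    """

    sites: pd.DataFrame
    maf_threshold: float
    min_allele_reads: int

    def __post_init__(self):
        self.sites = self.sites.sort_values(
            ["locus_id", "offset"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_loci_with_snps(self) -> int:
        return self.sites.locus_id.nunique()


def pool_equal_reads(per_population: dict[str, Reads], n_per_population: int,
                     seed: int = 0) -> Reads:
    """Uniform sample without replacement of exactly ``n_per_population``
    reads from each population, concatenated (populations in sorted name
    order so the draw is reproducible)."""
    rng = np.random.default_rng(seed)
    parts = []
    for name in sorted(per_population):
        reads = per_population[name]
        if len(reads) < n_per_population:
            raise ValueError(
                f"population {name!r} has {len(reads)} reads, "
                f"needs {n_per_population}")
        idx = np.sort(rng.choice(len(reads), n_per_population, replace=False))
        parts.append(reads.subset(idx))
    return Reads.concat(parts)


def call_snps(pileup: np.ndarray, maf_threshold: float,
              min_allele_reads: int = MIN_ALLELE_READS) -> SNPPanel:
    """Call bi-allelic SNPs from a pooled pileup array (n_loci, width, 4).

    Per column the base counts are ranked; the site is a SNP iff the top two
    bases each have >= ``min_allele_reads`` supporting reads, every other
    base has fewer, and minor/(major+minor) >= ``maf_threshold``. The MAF
    denominator is the top-two-allele depth, consistent with treating the
    site as bi-allelic. Count ties rank bases in A<C<G<T order.
    """
    if not 0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must lie in (0, 0.5]")
    n_loci, width, _ = pileup.shape
    # stable sort on negated counts: ties resolve to the smaller base code
    order = np.argsort(-pileup, axis=2, kind="stable")
    ranked = np.take_along_axis(pileup, order, axis=2)
    major, minor, third = ranked[..., 0], ranked[..., 1], ranked[..., 2]
    with np.errstate(invalid="ignore"):
        maf = np.where(major + minor > 0, minor / (major + minor), 0.0)
    is_snp = ((minor >= min_allele_reads) & (third < min_allele_reads)
              & (maf >= maf_threshold))
    locus_ids, offsets = np.nonzero(is_snp)
    sites = pd.DataFrame({
        "locus_id": locus_ids,
        "offset": offsets,
        "ref": [BASES[b] for b in order[locus_ids, offsets, 0]],
        "alt": [BASES[b] for b in order[locus_ids, offsets, 1]],
        "pool_maf": maf[locus_ids, offsets],
        "pool_depth": (major + minor)[locus_ids, offsets],
    })
    return SNPPanel(sites, maf_threshold, min_allele_reads)


def snp_position_histogram(panel: SNPPanel, read_length: int = 64) -> np.ndarray:
    """SNP counts per read offset 0..read_length-1; sums to the panel size.
    Flat profiles indicate no positional calling bias."""
    if len(panel) == 0:
        raise ValueError("empty panel")
    return np.bincount(panel.sites.offset, minlength=read_length)


def snps_per_locus(panel: SNPPanel) -> pd.Series:
    """Distribution of SNPs per locus: index = SNP count, value = number of
    loci carrying that many panel SNPs."""
    if len(panel) == 0:
        raise ValueError("empty panel")
    per_locus = panel.sites.groupby("locus_id").size()
    return per_locus.value_counts().sort_index()
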