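"""Sequencing-budget saturation analysis.

How many loci reach a given coverage as the number of sequenced reads
grows? Because per-locus amplification efficiencies are strongly shared
between samples, the curve — estimated by random read subsampling and
re-mapping — predicts the usable locus set at any budget. Frequent cutters
spread reads over many more loci than rare cutters, so the rare cutter
wins at small budgets and the frequent cutter at large ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapping import LocusIndex, MapResult, map_reads
from .reads import Reads

COVERAGE_THRESHOLDS = (5, 10, 20, 50)


def subsample_reads(reads: Reads, budget: int, seed: int = 0) -> Reads:
    """Uniform sample of exactly ``budget`` reads without replacement
    (reads are physical molecules; a subsampled lane has no duplicates)."""
    if budget > len(reads):
        raise ValueError(f"budget {budget} exceeds pool of {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), budget, replace=False))
    return reads.subset(idx)


def loci_at_coverage_curve(reads: Reads, index: LocusIndex, budgets,
                           thresholds=COVERAGE_THRESHOLDS,
                           seed: int = 0) -> pd.DataFrame:
    """Loci reaching each read-depth threshold at each budget.

    The full pool is mapped once; each budget then subsamples read indices
    and counts per-locus depths from the corresponding mapping assignments.
    Mapping is per-read, so this is identical to re-mapping every
    subsample, at a fraction of the cost. Budgets are nested (prefixes of
    one random permutation): each is still a uniform draw without
    replacement, and the curve is monotone in the budget by construction,
    as a physical sequencing run would be.
    """
    result = map_reads(reads, index)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(reads))
    n_loci = len(index.loci)
    rows = []
    for budget in sorted(budgets):
        if budget > len(reads):
            raise ValueError(f"budget {budget} exceeds read pool")
        take = perm[:budget]
        depth = np.bincount(result.locus[take][result.locus[take] >= 0],
                            minlength=n_loci)
        for t in thresholds:
            rows.append({"budget": budget, "threshold": t,
                         "n_loci": int((depth >= t).sum())})
    return pd.DataFrame(rows)


def locus_depths(result: MapResult, n_loci: int) -> np.ndarray:
    """Mapped-read count per locus."""
    mapped = result.locus[result.locus >= 0]
    return np.bincount(mapped, minlength=n_loci)


def cross_sample_coverage_correlation(depths: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-locus coverage between samples.

    ``depths``: loci x samples table, typically restricted to SNP-bearing
    loci (one row per locus). High off-diagonal correlation means the same
    loci are deeply sequenced in every sample, the prerequisite for
    genotyping a shared locus set.
    """
    if depths.shape[1] < 2:
        raise ValueError("need at least two samples")
    r = np.corrcoef(depths.to_numpy(), rowvar=False)
    return pd.DataFrame(r, index=depths.columns, columns=depths.columns)
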