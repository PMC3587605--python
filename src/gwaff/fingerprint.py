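"""Genome-wide allele frequency fingerprints (GWAFFs) and their analyses.

A fingerprint is the vector of variant-allele frequencies of one pooled
population sample across the reference SNP panel. This module computes the
fingerprints from per-sample pileups, tabulates how many panel sites are
genotypable at increasing coverage thresholds, quantifies reproducibility
between sampling replicates as a function of coverage, and discriminates
populations with PCA, including the dependence of separation on the number
of SNPs used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples, silhouette_score

from ._seq import BASES
from .panel import SNPPanel

MIN_COVERAGE = 5
COVERAGE_BINS = ((5, 10), (10, 20), (20, None))
GENOTYPE_THRESHOLDS = (5, 10, 15, 20, 25, 50)


@dataclass
class AFMatrix:
    """Samples x panel-sites variant-allele frequencies with coverage.

    ``af`` and ``cov`` are aligned DataFrames (rows = samples, columns =
    site labels); an AF cell is NaN exactly where coverage is below
    ``min_cov``. ``samples`` maps each row to its population and replicate.
    """

    af: pd.DataFrame
    cov: pd.DataFrame
    samples: pd.DataFrame  # columns: sample, population, replicate
    min_cov: int = MIN_COVERAGE

    def __post_init__(self):
        if not self.af.index.equals(self.cov.index) or \
                not self.af.columns.equals(self.cov.columns):
            raise ValueError("af and cov are not aligned")
        below = self.cov.to_numpy() < self.min_cov
        if not (np.isnan(self.af.to_numpy()) == below).all():
            raise ValueError("missingness does not match the coverage threshold")

    @property
    def n_samples(self) -> int:
        return self.af.shape[0]

    @property
    def n_sites(self) -> int:
        return self.af.shape[1]

    def complete_sites(self) -> pd.DataFrame:
        """AF restricted to sites called in every sample."""
        return self.af.dropna(axis=1)

    def for_population(self, population: str) -> "AFMatrix":
        rows = self.samples.population == population
        keep = self.samples.loc[rows, "sample"]
        return AFMatrix(self.af.loc[keep], self.cov.loc[keep],
                        self.samples.loc[rows].reset_index(drop=True),
                        self.min_cov)


def call_sample_af(pileup: np.ndarray, panel: SNPPanel,
                   min_cov: int = MIN_COVERAGE) -> pd.DataFrame:
    """One sample's fingerprint row: per panel site, coverage = ref+alt
    reads (other bases ignored), AF = alt/(ref+alt) when coverage reaches
    ``min_cov`` and missing (NaN) otherwise."""
    sites = panel.sites
    ref_codes = sites.ref.map(BASES.index).to_numpy()
    alt_codes = sites.alt.map(BASES.index).to_numpy()
    locus = sites.locus_id.to_numpy()
    if len(sites) and locus.max() >= pileup.shape[0]:
        raise ValueError("panel refers to loci absent from this pileup")
    offset = sites.offset.to_numpy()
    ref_n = pileup[locus, offset, ref_codes]
    alt_n = pileup[locus, offset, alt_codes]
    cov = ref_n + alt_n
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(cov >= min_cov, alt_n / np.maximum(cov, 1), np.nan)
    return pd.DataFrame({"cov": cov, "af": af},
                        index=site_labels(panel))


def site_labels(panel: SNPPanel) -> pd.Index:
    return pd.Index([f"L{l}:{o}" for l, o in
                     zip(panel.sites.locus_id, panel.sites.offset)],
                    name="site")


def build_af_matrix(pileups: dict[str, np.ndarray], panel: SNPPanel,
                    samples: pd.DataFrame,
                    min_cov: int = MIN_COVERAGE) -> AFMatrix:
    """Assemble the fingerprint matrix from per-sample pileups. ``samples``
    must have columns sample/population/replicate; rows follow its order."""
    af_rows, cov_rows = [], []
    for name in samples["sample"]:
        row = call_sample_af(pileups[name], panel, min_cov)
        af_rows.append(row["af"].to_numpy())
        cov_rows.append(row["cov"].to_numpy())
    index = pd.Index(samples["sample"], name="sample")
    cols = site_labels(panel)
    af = pd.DataFrame(np.array(af_rows), index=index, columns=cols)
    cov = pd.DataFrame(np.array(cov_rows), index=index, columns=cols)
    return AFMatrix(af, cov, samples.reset_index(drop=True), min_cov)


def genotyped_at_thresholds(matrix: AFMatrix,
                            thresholds=GENOTYPE_THRESHOLDS,
                            sample_fraction: float = 0.75) -> pd.Series:
    """Panel sites genotypable in at least ``sample_fraction`` of samples at
    each minimum-coverage threshold. Counts are non-increasing in the
    threshold."""
    need = math.ceil(sample_fraction * matrix.n_samples)
    cov = matrix.cov.to_numpy()
    counts = {t: int(((cov >= t).sum(axis=0) >= need).sum())
              for t in thresholds}
    return pd.Series(counts, name="n_sites").rename_axis("min_coverage")


def replicate_concordance(matrix: AFMatrix, bins=COVERAGE_BINS,
                          n_per_bin: int = 1000, seed: int = 0,
                          allow_fewer: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlation of replicate fingerprints by coverage bin.

    A site qualifies for a bin only if its coverage falls inside the bin in
    every replicate, so each bin isolates one coverage regime;
    ``n_per_bin`` qualifying sites are then sampled uniformly to equalise
    the comparisons. Returns one row per bin with the mean and SD over all
    replicate pairs.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    cov = matrix.cov.to_numpy()
    af = matrix.af.to_numpy()
    rows = []
    for lo, hi in bins:
        in_bin = (cov >= lo) if hi is None else ((cov >= lo) & (cov < hi))
        qualify = np.flatnonzero(in_bin.all(axis=0))
        if qualify.size == 0:
            raise ValueError(f"no sites with coverage in [{lo}, {hi}) "
                             "across all replicates")
        if qualify.size < n_per_bin:
            if not allow_fewer:
                raise ValueError(
                    f"only {qualify.size} qualifying sites in bin [{lo}, {hi})"
                    f", need {n_per_bin} (pass allow_fewer=True to proceed)")
            chosen = qualify
        else:
            chosen = rng.choice(qualify, n_per_bin, replace=False)
        sub = af[:, chosen]
        pair_r = [np.corrcoef(sub[i], sub[j])[0, 1]
                  for i, j in combinations(range(matrix.n_samples), 2)]
        rows.append({"bin_low": lo, "bin_high": hi, "n_sites": chosen.size,
                     "mean_r": float(np.mean(pair_r)),
                     "sd_r": float(np.std(pair_r, ddof=1)),
                     "n_pairs": len(pair_r)})
    return pd.DataFrame(rows)


def concordance_attenuation(true_af: np.ndarray, coverage: float) -> float:
    """Closed-form expected Pearson r between two replicate fingerprints
    read at binomial coverage c: r = Var(p) / (Var(p) + E[p(1-p)]/c),
    the classical attenuation of correlation by binomial sampling noise."""
    p = np.asarray(true_af, dtype=float)
    var_p = p.var()
    noise = (p * (1 - p)).mean() / coverage
    return float(var_p / (var_p + noise))


@dataclass
class PCAResult:
    scores: pd.DataFrame              # samples x components
    variance_ratio: np.ndarray        # fractions, sum to 1 over all comps
    n_sites: int
    samples: pd.DataFrame

    def silhouette(self, n_components: int = 2) -> float:
        """Mean silhouette of population labels on the leading components
        (the separation score; invariant to component sign flips)."""
        x = self.scores.iloc[:, :n_components].to_numpy()
        return float(silhouette_score(x, self.samples.population))

    def silhouette_by_population(self, n_components: int = 2) -> pd.Series:
        x = self.scores.iloc[:, :n_components].to_numpy()
        s = silhouette_samples(x, self.samples.population)
        return pd.Series(s, index=self.samples.population).groupby(level=0).mean()


def pca_fingerprint(matrix: AFMatrix) -> PCAResult:
    """PCA of the fingerprints over complete-case sites (AF called in every
    sample). Columns are centred but not scaled to unit variance — allele
    frequencies already share the [0, 1] scale. Scores are deterministic up
    to component sign."""
    complete = matrix.complete_sites()
    if complete.shape[1] == 0:
        raise ValueError("no sites with complete allele-frequency calls")
    if complete.shape[1] < matrix.n_samples:
        warnings.warn("fewer complete sites than samples; components are "
                      "poorly determined", stacklevel=2)
    x = complete.to_numpy()
    n_comp = min(x.shape[0] - 1, x.shape[1])  # centring removes one df
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(pd.DataFrame(scores, index=complete.index, columns=cols),
                     model.explained_variance_ratio_,
                     complete.shape[1], matrix.samples)


def snp_subsample_separation(matrix: AFMatrix, n_sites_list=(
        500, 1000, 1500, 2000, 4000, 6000, 8000, 10000),
        seed: int = 0) -> pd.DataFrame:
    """Separation score as a function of panel size: for each n, draw n
    complete-case sites without replacement, run the PCA and score the mean
    silhouette of population labels on the first two components."""
    complete = matrix.complete_sites()
    available = complete.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_sites_list:
        if n > available:
            raise ValueError(f"{n} sites requested, {available} available")
        cols = rng.choice(available, n, replace=False)
        sub = AFMatrix(complete.iloc[:, np.sort(cols)],
                       matrix.cov[complete.columns[np.sort(cols)]],
                       matrix.samples, matrix.min_cov)
        res = pca_fingerprint(sub)
        rows.append({"n_sites": n, "silhouette": res.silhouette(),
                     "pc1_variance": float(res.variance_ratio[0])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# site-level simulation (exactly known coverage, for oracle experiments)


def simulate_af_matrix(true_af: np.ndarray, coverage, n_replicates: int,
                       seed: int = 0, population: str = "pop",
                       min_cov: int = MIN_COVERAGE) -> AFMatrix:
    """Replicate fingerprints drawn directly at site level: each replicate
    reads every site at the given coverage (scalar or per-site array) and
    observes Binomial(c, p)/c. Bypasses reads entirely, so closed-form
    oracles for attenuation and accuracy apply exactly."""
    p = np.asarray(true_af, dtype=float)
    c = np.broadcast_to(np.asarray(coverage), p.shape).astype(int)
    rng = np.random.default_rng(seed)
    names = [f"{population}_rep{r + 1}" for r in range(n_replicates)]
    af = np.stack([rng.binomial(c, p) / np.maximum(c, 1)
                   for _ in names])
    af = np.where(c >= min_cov, af, np.nan)
    cols = pd.Index([f"S{j}" for j in range(p.size)], name="site")
    samples = pd.DataFrame({"sample": names, "population": population,
                            "replicate": range(1, n_replicates + 1)})
    return AFMatrix(pd.DataFrame(af, index=names, columns=cols),
                    pd.DataFrame(np.tile(c, (n_replicates, 1)),
                                 index=names, columns=cols),
                    samples, min_cov)


def af_accuracy(af: np.ndarray, cov: np.ndarray, truth: np.ndarray,
                bin_edges=(5, 10, 20, 40, 80, 160, 320, np.inf)) -> pd.DataFrame:
    """Bias and RMSE of AF calls against truth, binned by coverage.

    Cells (flattened sample x site entries) with missing AF are ignored.
    Returns one row per coverage bin with mean coverage, bias, its standard
    error, RMSE and the cell count.
    """
    af, cov, truth = (np.asarray(a, dtype=float).ravel()
                      for a in (af, cov, truth))
    ok = ~np.isnan(af) & ~np.isnan(truth)
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        cells = ok & (cov >= lo) & (cov < hi)
        n = int(cells.sum())
        if n == 0:
            continue
        err = af[cells] - truth[cells]
        rows.append({"cov_low": lo, "cov_high": hi,
                     "mean_cov": float(cov[cells].mean()),
                     "bias": float(err.mean()),
                     "bias_se": float(err.std(ddof=1) / np.sqrt(n)) if n > 1
                     else np.nan,
                     "rmse": float(np.sqrt((err ** 2).mean())), "n": n})
    return pd.DataFrame(rows)


def rmse_loglog_slope(accuracy: pd.DataFrame) -> float:
    """Least-squares slope of log RMSE on log mean coverage; binomial
    sampling noise alone gives -1/2."""
    from scipy.stats import linregress
    acc = accuracy[accuracy.rmse > 0]
    fit = linregress(np.log(acc.mean_cov), np.log(acc.rmse))
    return float(fit.slope)
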