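"""Canned recovery experiments: simulate a study, run the pipeline, and
compare what comes out against the generator's ground truth.

Each experiment is a single seeded function returning plain dicts/frames,
so the same code drives the test suite and the reproduction script. The
default arguments are the study conditions; the docstrings state the
oracle each experiment is checked against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import poisson

from . import fingerprint as fp
from . import panel as pnl
from . import preprocess as pre
from . import saturation as sat
from . import simulate as sim
from ._seq import BASES
from .assemble import LocusSet, assemble_loci
from .mapping import LocusIndex, MapResult, build_pileup, map_reads
from .pipeline import load_config, simulate_experiment, stage_seed
from .reads import Reads


def _truth_locus_set(fragments, pops, locus_len: int = 64):
    """LocusSet built directly from the error-free fragment-end templates
    (the loci a perfect assembly would produce), plus the truth records."""
    truth = sim.build_truth_loci(fragments, pops, locus_len)
    consensus = np.stack([t.template for t in truth])
    order = np.lexsort(consensus.T[::-1])
    consensus = consensus[order]
    truth = [truth[i] for i in order]
    loci = LocusSet(consensus, np.zeros(len(truth), np.int64),
                    [[] for _ in truth])
    return loci, truth


def panel_truth_af(panel: pnl.SNPPanel, locus_match: np.ndarray,
                   truth_loci: list, pops: list) -> np.ndarray:
    """True alternate-allele frequency of each panel site in each
    population, oriented to the panel's ref/alt; NaN where the panel site
    does not correspond to a simulated variant (a false positive) or its
    locus could not be matched to truth."""
    out = np.full((len(pops), len(panel)), np.nan)
    for i, row in enumerate(panel.sites.itertuples()):
        t = int(locus_match[row.locus_id])
        if t < 0:
            continue
        site = truth_loci[t].sites.get(int(row.offset))
        if site is None:
            continue
        ref_code, alt_code, j = site
        pr, pa = BASES.index(row.ref), BASES.index(row.alt)
        if {pr, pa} != {ref_code, alt_code}:
            continue
        for k, pop in enumerate(pops):
            af = pop.true_af[j]
            out[k, i] = af if pa == alt_code else 1.0 - af
    return out


def af_recovery_experiment(seed: int, n_populations: int = 2,
                           n_replicates: int = 4,
                           genome_length: int = 1_000_000,
                           n_reads_per_sample: int = 200_000,
                           error_rate: float = 0.002,
                           maf_threshold: float = 0.05,
                           budgets=(1000, 3000, 10_000, 30_000,
                                    100_000, 200_000),
                           n_pool_per_population: int = 20_000,
                           min_cov: int = 5) -> dict:
    """Full-pipeline allele-frequency recovery against ground truth.

    Simulates a rare-cutter lane (populations x sampling replicates, one
    barcode per sample), runs demultiplex -> preprocess -> assembly ->
    panel -> fingerprints, and scores the AF calls against the generating
    pool frequencies. Coverage-resolved error is measured by sweeping
    sequencing budgets (per-sample read subsampling), pooling
    (coverage, error) cells across budgets, and binning by coverage; with
    binomial read sampling the RMSE in coverage bin c falls as c^{-1/2}.
    """
    cfg = {
        "seed": seed,
        "genome": {"length": genome_length, "gc": 0.5},
        "enzyme": "PstI",
        "populations": {"n": n_populations, "n_founders": 24,
                        "snp_density": 0.01, "fst": 0.05},
        "library": {"replicates": n_replicates,
                    "n_reads_per_sample": n_reads_per_sample,
                    "barcodes": {"n": n_populations * n_replicates,
                                 "lengths": [4, 8],
                                 "efficiency_sigma": 0.3}},
        "sim": {"substitution_error_rate": error_rate},
    }
    world = simulate_experiment(load_config(cfg))
    samples = world["samples"]
    pops = world["populations"]

    demux = pre.demultiplex(world["lane"], world["barcodes"])
    stats = pre.read_count_stats(demux.counts)
    processed = {row["sample"]: pre.preprocess_reads(
        demux.by_barcode[row.barcode]) for _, row in samples.iterrows()}

    loci = assemble_loci(Reads.concat(list(processed.values())))
    index = LocusIndex(loci)

    by_pop = {}
    for pop in samples.population.unique():
        names = samples.loc[samples.population == pop, "sample"]
        by_pop[pop] = Reads.concat([processed[n] for n in names])
    # pool sized for a few-hundred-fold per-locus depth: the regime the
    # bi-allelic min-allele-read rule is designed for (at tens of
    # thousands-fold, sequencing-error bases alone exceed the third-allele
    # cap and the rule would reject clean sites)
    n_pool = min(n_pool_per_population,
                 min(len(r) for r in by_pop.values()))
    pooled = pnl.pool_equal_reads(by_pop, n_pool, stage_seed(seed, "pool"))
    pool_pileup = build_pileup(pooled, map_reads(pooled, index), loci)
    panel5 = pnl.call_snps(pool_pileup, maf_threshold)
    panel1 = pnl.call_snps(pool_pileup, 0.01)

    truth_loci = sim.build_truth_loci(world["fragments"], pops)
    # consensus bases flip to the alternate allele wherever pooled af > 1/2,
    # so allow several mismatches; templates are far apart, matches stay
    # unambiguous
    match = sim.match_loci_to_truth(loci.consensus, truth_loci, max_dist=8)
    truth_af = panel_truth_af(panel5, match, truth_loci, pops)
    pop_names = [p.name for p in pops]
    sample_truth = truth_af[[pop_names.index(p) for p in samples.population]]

    # full-depth fingerprints: bias of AF calls against the pool truth
    results = {n: map_reads(r, index) for n, r in processed.items()}
    pileups = {n: build_pileup(processed[n], results[n], loci)
               for n in processed}
    matrix = fp.build_af_matrix(pileups, panel5, samples, min_cov)
    err = matrix.af.to_numpy() - sample_truth
    cells = ~np.isnan(err)
    bias = float(np.nanmean(err))
    bias_se = float(np.nanstd(err, ddof=1) / np.sqrt(cells.sum()))
    # cells at one site share the true frequency and any systematic mapping
    # loss, so the honest SE for the mean bias clusters by site
    site_n = (~np.isnan(err)).sum(axis=0)
    site_sums = np.where(np.isnan(err), 0.0, err).sum(axis=0)
    site_means = site_sums[site_n > 0] / site_n[site_n > 0]
    bias_se_site = float(site_means.std(ddof=1) / np.sqrt(site_means.size)) \
        if site_means.size > 1 else float("nan")

    # budget sweep: same mapping, subsampled read sets, coverage-binned error
    sweep_af, sweep_cov, sweep_truth = [], [], []
    rng = np.random.default_rng(stage_seed(seed, "sweep"))
    for si, name in enumerate(samples["sample"]):
        reads, res = processed[name], results[name]
        perm = rng.permutation(len(reads))
        for b in budgets:
            if b > len(reads):
                b = len(reads)
            take = perm[:b]
            sub = build_pileup(reads.subset(take),
                               MapResult(res.locus[take], res.reverse[take]),
                               loci)
            row = fp.call_sample_af(sub, panel5, min_cov)
            sweep_af.append(row["af"].to_numpy())
            sweep_cov.append(row["cov"].to_numpy())
            sweep_truth.append(sample_truth[si])
    accuracy = fp.af_accuracy(
        np.concatenate(sweep_af), np.concatenate(sweep_cov),
        np.concatenate(sweep_truth),
        bin_edges=(5, 10, 20, 40, 80, 160, 320, 640, 1280, np.inf))
    # fit the power law over the coverage range where read sampling
    # dominates (the genotyping regime, <= a few hundred fold); far above
    # it the error-driven noise floor flattens the curve
    slope = fp.rmse_loglog_slope(accuracy[accuracy.cov_high <= 640])

    flat_err = np.concatenate(sweep_af) - np.concatenate(sweep_truth)
    flat_cov = np.concatenate(sweep_cov)
    low = ~np.isnan(flat_err) & (flat_cov >= 5) & (flat_cov < 10)
    high = ~np.isnan(flat_err) & (flat_cov >= 20)
    n_fp = int(np.isnan(truth_af[0]).sum())
    return {
        "n_fragments": len(world["fragments"]),
        "n_loci": len(loci),
        "n_loci_matching_truth": int((match >= 0).sum()),
        "read_count_cv": stats["cv"],
        "n_snps_maf5": len(panel5), "n_snps_maf1": len(panel1),
        "n_false_positive_sites": n_fp,
        "bias": bias, "bias_se": bias_se, "bias_se_site": bias_se_site,
        "n_sites_with_truth": int(site_means.size),
        "n_cells": int(cells.sum()),
        "accuracy": accuracy, "rmse_loglog_slope": slope,
        "rmse_cov_5_10": float(np.sqrt(np.mean(flat_err[low] ** 2))),
        "rmse_cov_ge20": float(np.sqrt(np.mean(flat_err[high] ** 2))),
        "matrix": matrix, "panel": panel5, "truth": sample_truth,
    }


def _quantized_beta(rng: np.random.Generator, n: int, n_founders: int = 24,
                    beta_shape=(0.8, 0.8)) -> np.ndarray:
    p = rng.beta(*beta_shape, size=n)
    return np.clip(np.rint(p * n_founders), 1, n_founders - 1) / n_founders


def concordance_attenuation_experiment(seed: int, coverages=(7, 14, 40),
                                       n_sites_per_bin: int = 1000,
                                       n_replicates: int = 4,
                                       n_rounds: int = 8) -> pd.DataFrame:
    """Replicate concordance by coverage bin against the attenuation oracle.

    Sites are read at fixed coverage c per bin (7, 14 and 40 fall in the
    bins [5,10), [10,20), [20,inf)); replicate AFs are Binomial(c, p)/c.
    The expected between-replicate Pearson r is the attenuation closed form
    Var(p)/(Var(p) + E[p(1-p)]/c). One row per bin: grand-mean observed r
    over rounds, its standard error, and the oracle value.
    """
    bins = tuple((lo, hi) for lo, hi in ((5, 10), (10, 20), (20, None)))
    per_round = {b: [] for b in bins}
    oracle = {b: [] for b in bins}
    for r in range(n_rounds):
        rng = np.random.default_rng(stage_seed(seed, f"conc{r}"))
        p = _quantized_beta(rng, n_sites_per_bin * len(coverages))
        cov = np.repeat(coverages, n_sites_per_bin)
        matrix = fp.simulate_af_matrix(p, cov, n_replicates,
                                       stage_seed(seed, f"conc-draw{r}"))
        table = fp.replicate_concordance(matrix, bins=bins,
                                         n_per_bin=n_sites_per_bin,
                                         seed=stage_seed(seed, f"conc-pick{r}"))
        for (lo, hi), mean_r, c in zip(bins, table.mean_r, coverages):
            per_round[(lo, hi)].append(mean_r)
            block = p[cov == c]
            oracle[(lo, hi)].append(fp.concordance_attenuation(block, c))
    rows = []
    for (lo, hi), c in zip(bins, coverages):
        obs = np.array(per_round[(lo, hi)])
        rows.append({"bin_low": lo, "bin_high": hi, "coverage": c,
                     "mean_r": obs.mean(),
                     "se": obs.std(ddof=1) / np.sqrt(n_rounds),
                     "oracle_r": float(np.mean(oracle[(lo, hi)]))})
    return pd.DataFrame(rows)


def _sequenceable_world(seed: int, enzyme: sim.Enzyme, genome_length: int,
                        cfg: sim.SimConfig):
    genome = sim.generate_genome(genome_length, 0.5, stage_seed(seed, "g"))
    frags = sim.select_fragments(sim.digest(genome, enzyme),
                                 cfg.min_fragment, cfg.max_fragment)
    weights = sim.assign_fragment_weights(frags, cfg, stage_seed(seed, "w"))
    pop = sim.make_population(genome, seed=stage_seed(seed, "p"))
    return genome, frags, weights, pop


def _processed_reads(pop, frags, weights, n_reads, cfg, seed) -> Reads:
    """Simulated reads taken through demultiplex + preprocess (one barcode)."""
    barcode = "ACGT"
    raw = sim.generate_reads(pop, frags, weights, barcode, n_reads, cfg, seed)
    demux = pre.demultiplex(raw, sim.BarcodeSet([(barcode, 1.0)]))
    return pre.preprocess_reads(demux.by_barcode[barcode])


def poisson_occupancy_experiment(seed: int, genome_length: int = 400_000,
                                 budgets=(150, 400, 1500, 4000),
                                 thresholds=(5, 10, 20, 50)) -> pd.DataFrame:
    """Saturation curve under uniform locus weights vs Poisson occupancy.

    With no amplification bias (sigma 0, no length bias, no error) reads
    spread uniformly over the L fragment-end loci, so the number of loci at
    depth >= c under budget b has mean ~ L*P(Poisson(b/L) >= c) and SD
    ~ sqrt(L*q*(1-q)). Returns observed and expected counts per
    (budget, threshold)."""
    cfg = sim.SimConfig(locus_lognormal_sigma=0.0,
                        length_bias_scale=np.inf,
                        substitution_error_rate=0.0,
                        low_quality_fraction=0.0)
    genome, frags, weights, pop = _sequenceable_world(
        seed, cfg.enzyme, genome_length, cfg)
    reads = _processed_reads(pop, frags, weights, max(budgets), cfg,
                             stage_seed(seed, "reads"))
    loci, _ = _truth_locus_set(frags, [pop])
    curve = sat.loci_at_coverage_curve(reads, LocusIndex(loci), budgets,
                                       thresholds, stage_seed(seed, "sub"))
    n_loci = len(loci)
    lam = curve.budget / n_loci
    q = poisson.sf(curve.threshold - 1, lam)
    curve["expected"] = n_loci * q
    curve["sd"] = np.sqrt(n_loci * q * (1 - q))
    return curve


def cutter_crossover_experiment(seed: int, genome_length: int = 400_000,
                                budgets=(500, 2000, 8000, 30_000, 60_000),
                                threshold: int = 5) -> pd.DataFrame:
    """Frequent vs rare cutter saturation on one genome.

    The rare cutter concentrates the same budget on far fewer loci, so it
    genotypes more loci at small budgets; the frequent cutter has far more
    loci available and overtakes once the budget covers them. Returns loci
    at ``threshold``-fold coverage per (enzyme, budget)."""
    frames = []
    for enzyme in (sim.PSTI, sim.APEKI):
        cfg = sim.SimConfig(enzyme=enzyme, low_quality_fraction=0.0)
        genome, frags, weights, pop = _sequenceable_world(
            seed, enzyme, genome_length, cfg)
        reads = _processed_reads(pop, frags, weights,
                                 int(max(budgets) * 1.01) + 50, cfg,
                                 stage_seed(seed, f"reads-{enzyme.name}"))
        loci, _ = _truth_locus_set(frags, [pop])
        curve = sat.loci_at_coverage_curve(
            reads, LocusIndex(loci), budgets, (threshold,),
            stage_seed(seed, f"sub-{enzyme.name}"))
        curve["enzyme"] = enzyme.name
        curve["n_available_loci"] = len(loci)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def discrimination_experiment(seed: int, n_pops: int = 8,
                              n_replicates: int = 4, n_sites: int = 12_000,
                              fst: float = 0.05, coverage_floor: int = 5,
                              coverage_extra_mean: float = 10.0,
                              n_sites_list=(500, 1000, 2000, 4000,
                                            6000, 8000, 10_000),
                              n_rounds: int = 10) -> dict:
    """Population discrimination by PCA and its dependence on panel size.

    Balding-Nichols population frequencies; every site read in every sample
    at coverage 5 + Poisson(10) (complete case by construction); replicate
    fingerprints are binomial draws. Reports the per-population silhouette
    of the full-panel PCA and the seed-averaged silhouette-vs-panel-size
    curve, which should rise as more sites average out read-sampling noise.
    """
    curves, sil_rows, pc1 = [], [], []
    for r in range(n_rounds):
        rng = np.random.default_rng(stage_seed(seed, f"disc{r}"))
        pop_af = sim.balding_nichols_af(n_pops, n_sites, fst, rng)
        names, pops_col, reps_col, af_rows, cov_rows = [], [], [], [], []
        for k in range(n_pops):
            for rep in range(n_replicates):
                cov = coverage_floor + rng.poisson(coverage_extra_mean,
                                                   n_sites)
                af_rows.append(rng.binomial(cov, pop_af[k]) / cov)
                cov_rows.append(cov)
                names.append(f"pop{k}_rep{rep + 1}")
                pops_col.append(f"pop{k}")
                reps_col.append(rep + 1)
        cols = pd.Index([f"S{j}" for j in range(n_sites)], name="site")
        samples = pd.DataFrame({"sample": names, "population": pops_col,
                                "replicate": reps_col})
        matrix = fp.AFMatrix(
            pd.DataFrame(np.array(af_rows), index=names, columns=cols),
            pd.DataFrame(np.array(cov_rows), index=names, columns=cols),
            samples, min_cov=coverage_floor)
        full = fp.pca_fingerprint(matrix)
        sil_rows.append(full.silhouette_by_population())
        pc1.append(float(full.variance_ratio[0]))
        curves.append(fp.snp_subsample_separation(
            matrix, n_sites_list, stage_seed(seed, f"disc-sub{r}")))
    curve = (pd.concat(curves).groupby("n_sites", as_index=False)
             .agg(silhouette=("silhouette", "mean"),
                  sd=("silhouette", "std")))
    return {"curve": curve,
            "silhouette_by_population": pd.concat(sil_rows, axis=1).mean(axis=1),
            "pc1_variance": float(np.mean(pc1)),
            "n_rounds": n_rounds}
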