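"""End-to-end pipeline: simulate -> demultiplex -> assemble -> map -> panel
-> fingerprints -> concordance/PCA -> saturation, driven by one YAML config
with a single global seed. Per-stage seeds derive deterministically from
the global seed and the stage name, so reruns are bit-identical."""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assemble as asm
from . import fingerprint as fp
from . import io as gio
from . import panel as pnl
from . import preprocess as pre
from . import saturation as sat
from . import simulate as sim
from .mapping import LocusIndex, build_pileup, map_reads
from .reads import Reads, write_fastq

log = logging.getLogger("gwaff")

DEFAULT_CONFIG = {
    "seed": 0,
    "genome": {"length": 200_000, "gc": 0.5},
    "enzyme": "PstI",
    "populations": {"n": 2, "n_founders": 24, "snp_density": 0.01,
                    "fst": 0.05},
    "library": {"replicates": 2, "n_reads_per_sample": 20_000,
                "barcodes": {"n": 32, "lengths": [4, 8],
                             "efficiency_sigma": 0.3}},
    "sim": {},
    "panel": {"maf_threshold": 0.05, "min_allele_reads": 5,
              "n_per_population": None},
    "fingerprint": {"min_cov": 5},
    "concordance": {"n_per_bin": 200, "allow_fewer": True},
    "saturation": {"budgets": [1000, 2000, 5000, 10000, 20000],
                   "thresholds": [5, 10, 20, 50]},
    "write_fastq": False,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            for k2, v2 in value.items():
                if k2 not in cfg[key] and key != "sim":
                    raise ValueError(f"unknown config key {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = value
    if isinstance(cfg["enzyme"], str):
        if cfg["enzyme"] not in sim.ENZYMES:
            raise ValueError(f"unknown enzyme {cfg['enzyme']!r}")
    return cfg


def _enzyme(cfg) -> sim.Enzyme:
    spec = cfg["enzyme"]
    if isinstance(spec, str):
        return sim.ENZYMES[spec]
    return sim.Enzyme(spec["name"], spec["recognition"], spec["cut_offset"])


def simulate_experiment(cfg: dict) -> dict:
    """Simulate one multiplexed lane per the config; returns the lane reads
    plus every piece of ground truth needed for recovery analyses."""
    seed = cfg["seed"]
    enzyme = _enzyme(cfg)
    sim_cfg = sim.SimConfig(enzyme=enzyme, **cfg["sim"])
    genome = sim.generate_genome(cfg["genome"]["length"], cfg["genome"]["gc"],
                                 stage_seed(seed, "genome"))
    fragments = sim.select_fragments(sim.digest(genome, enzyme),
                                     sim_cfg.min_fragment, sim_cfg.max_fragment)
    if not fragments:
        raise ValueError("no sequenceable fragments; enlarge the genome")
    weights = sim.assign_fragment_weights(fragments, sim_cfg,
                                          stage_seed(seed, "weights"))
    pcfg = cfg["populations"]
    pops = sim.make_populations(genome, pcfg["n"], pcfg["n_founders"],
                                pcfg["snp_density"], pcfg["fst"],
                                stage_seed(seed, "populations"))
    lib = cfg["library"]
    bcfg = lib["barcodes"]
    barcodes = sim.make_barcode_set(bcfg["n"], tuple(bcfg["lengths"]),
                                    stage_seed(seed, "barcodes"),
                                    bcfg["efficiency_sigma"])
    samples = []
    for p, pop in enumerate(pops):
        for r in range(lib["replicates"]):
            samples.append({"sample": f"{pop.name}_rep{r + 1}",
                            "population": pop.name, "replicate": r + 1,
                            "pop_index": p})
    if len(samples) > len(barcodes):
        raise ValueError("more samples than barcodes")
    samples = pd.DataFrame(samples)
    samples["barcode"] = barcodes.sequences[:len(samples)]

    # barcode efficiency modulates how many lane reads each sample yields
    rng = np.random.default_rng(stage_seed(seed, "lane"))
    eff = barcodes.weights[:len(samples)]
    total = lib["n_reads_per_sample"] * len(samples)
    per_sample = rng.multinomial(total, eff / eff.sum())
    parts = []
    for i, row in samples.iterrows():
        parts.append(sim.generate_reads(
            pops[row.pop_index], fragments, weights, row.barcode,
            int(per_sample[i]), sim_cfg,
            stage_seed(seed, f"reads:{row['sample']}")))
    lane = Reads.concat(parts)
    log.info("simulated %d reads over %d samples, %d fragments",
             len(lane), len(samples), len(fragments))
    return {"lane": lane, "samples": samples, "barcodes": barcodes,
            "populations": pops, "fragments": fragments, "weights": weights,
            "genome": genome, "sim_cfg": sim_cfg}


def run_pipeline(config, outdir) -> dict:
    """Execute the configured pipeline and write all artifacts to
    ``outdir``. Returns the in-memory results keyed by stage."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    world = simulate_experiment(cfg)
    samples, lane = world["samples"], world["lane"]

    demux = pre.demultiplex(lane, world["barcodes"])
    demux.counts.to_csv(outdir / "read_counts.tsv", sep="\t", index=False)
    processed = {row["sample"]: pre.preprocess_reads(demux.by_barcode[row.barcode])
                 for _, row in samples.iterrows()}
    n_proc = sum(len(r) for r in processed.values())
    log.info("preprocess kept %d/%d reads", n_proc, len(lane))

    loci = asm.assemble_loci(Reads.concat(list(processed.values())))
    gio.write_loci_fasta(loci, outdir / "loci.fasta")
    gio.write_locus_depths(loci, outdir / "locus_depths.tsv")
    log.info("assembled %d loci (secondary aligned %d, dropped %d)",
             len(loci), loci.n_secondary_aligned, loci.n_secondary_dropped)

    index = LocusIndex(loci)
    by_pop: dict[str, Reads] = {}
    for pop in samples.population.unique():
        names = samples.loc[samples.population == pop, "sample"]
        by_pop[pop] = Reads.concat([processed[n] for n in names])
    pan_cfg = cfg["panel"]
    n_pool = pan_cfg["n_per_population"] or min(len(r) for r in by_pop.values())
    pooled = pnl.pool_equal_reads(by_pop, n_pool, stage_seed(seed, "pool"))
    pool_pileup = build_pileup(pooled, map_reads(pooled, index), loci)
    panel = pnl.call_snps(pool_pileup, pan_cfg["maf_threshold"],
                          pan_cfg["min_allele_reads"])
    gio.write_panel_tsv(panel, outdir / "panel.tsv")
    gio.write_panel_vcf(panel, loci, outdir / "panel.vcf")
    log.info("panel: %d SNPs on %d loci", len(panel), panel.n_loci_with_snps)

    pileups, depth_cols = {}, {}
    for name, reads in processed.items():
        res = map_reads(reads, index)
        pileups[name] = build_pileup(reads, res, loci)
        depth_cols[name] = sat.locus_depths(res, len(loci))
    matrix = fp.build_af_matrix(pileups, panel, samples,
                                cfg["fingerprint"]["min_cov"])
    gio.write_af_matrix(matrix, outdir / "af_matrix")
    thresholds = fp.genotyped_at_thresholds(matrix)
    thresholds.to_csv(outdir / "genotyped_at_thresholds.tsv", sep="\t")

    results = {"config": cfg, "samples": samples, "loci": loci,
               "panel": panel, "matrix": matrix, "thresholds": thresholds,
               "world": world, "read_counts": demux.counts}

    conc_rows = []
    for pop in samples.population.unique():
        sub = matrix.for_population(pop)
        if sub.n_samples < 2:
            continue
        try:
            conc = fp.replicate_concordance(
                sub, n_per_bin=cfg["concordance"]["n_per_bin"],
                seed=stage_seed(seed, f"conc:{pop}"),
                allow_fewer=cfg["concordance"]["allow_fewer"])
            conc["population"] = pop
            conc_rows.append(conc)
        except ValueError as exc:
            log.warning("concordance skipped for %s: %s", pop, exc)
    if conc_rows:
        concordance = pd.concat(conc_rows, ignore_index=True)
        concordance.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        results["concordance"] = concordance

    try:
        pca = fp.pca_fingerprint(matrix)
        pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.Series(pca.variance_ratio, name="variance_ratio").to_csv(
            outdir / "pca_variance.tsv", sep="\t")
        results["pca"] = pca
    except ValueError as exc:
        log.warning("PCA skipped: %s", exc)

    pool_all = Reads.concat(list(processed.values()))
    budgets = [b for b in cfg["saturation"]["budgets"] if b <= len(pool_all)]
    if budgets:
        curve = sat.loci_at_coverage_curve(
            pool_all, index, budgets,
            tuple(cfg["saturation"]["thresholds"]),
            stage_seed(seed, "saturation"))
        curve.to_csv(outdir / "saturation.tsv", sep="\t", index=False)
        results["saturation"] = curve

    snp_loci = sorted(panel.sites.locus_id.unique())
    depths = pd.DataFrame(depth_cols).iloc[snp_loci]
    if depths.shape[1] >= 2 and len(snp_loci) >= 2:
        corr = sat.cross_sample_coverage_correlation(depths)
        corr.to_csv(outdir / "coverage_correlation.tsv", sep="\t")
        results["coverage_correlation"] = corr

    if cfg["write_fastq"]:
        write_fastq(lane, outdir / "lane.fastq")

    stamp = {"seed": seed,
             "config_sha256": hashlib.sha256(
                 json.dumps(cfg, sort_keys=True).encode()).hexdigest()}
    (outdir / "run_info.json").write_text(json.dumps(stamp, indent=2))
    return results
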