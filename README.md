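# gwaff — genome-wide allele frequency fingerprints from pooled GBS

`gwaff` genotypes *populations* rather than individuals. Outbreeding crops
such as forage grasses are sold as synthetic varieties: pools of many
founder haplotypes that cannot be characterised by any single plant's
genotype. Sequencing a pooled DNA sample of such a population through
genotyping-by-sequencing (GBS) — restriction-enzyme complexity reduction
with inline-barcoded, multiplexed single-end reads — yields, at every SNP,
an estimate of the population's allele frequency. The vector of these
frequencies across a genome-wide panel is the population's **GWAFF**
(genome-wide allele frequency fingerprint): a reproducible signature that
separates varieties by PCA, without any reference genome.

The package implements the full pipeline and a synthetic pooled-GBS data
generator with known ground truth:

1. **simulate** — restriction digestion of a genome (IUPAC motifs with
   degenerate positions), size selection, polycross populations with
   Balding–Nichols divergence, fragment-level amplification bias, barcoded
   101 bp reads with substitution errors;
2. **preprocess** — exact-prefix demultiplexing of variable-length
   barcodes, hard trim to 64 bp, adapter clipping, the 95%-of-bases-≥Q15
   filter, per-sample read-count statistics (CV);
3. **assemble** — de-novo consensus loci by exact-stack clustering
   (depth ≥ 3) and connected-component merging at Hamming distance ≤ 2,
   with secondary-read attachment at distance ≤ 4;
4. **map** — ungapped unique mapping with ≤ 2 mismatches (`-v 2 -m 1`
   semantics), both orientations, base-count pileups;
5. **panel** — bi-allelic SNP calling from an equal-read pool of all
   populations (MAF ≥ 1% or 5%, ≥ 5 reads per allele, third allele < 5);
6. **fingerprint** — per-sample allele frequencies at coverage ≥ 5,
   genotypability at thresholds 5–50×, replicate concordance by coverage
   bin, PCA and SNP-subsampling separation curves;
7. **saturation** — loci genotypable at 5/10/20/50× as a function of
   sequencing budget, and cross-sample locus-coverage correlation.

The estimator behind every fingerprint cell is simply

    AF = n_alt / (n_ref + n_alt),   reported when n_ref + n_alt >= 5,

whose reproducibility between sampling replicates at coverage c follows the
attenuation law r = Var(p) / (Var(p) + E[p(1−p)]/c) — the quantity the
concordance analysis measures and tests.

## Worked example

```python
from gwaff.pipeline import run_pipeline

results = run_pipeline({
    "seed": 7,
    "genome": {"length": 600_000, "gc": 0.5},
    "library": {"replicates": 2, "n_reads_per_sample": 30_000,
                "barcodes": {"n": 8, "lengths": [4, 8],
                             "efficiency_sigma": 0.3}},
    "panel": {"maf_threshold": 0.05, "min_allele_reads": 5,
              "n_per_population": 20_000},
    "concordance": {"n_per_bin": 50, "allow_fewer": True},
}, "demo_out")

print(len(results["loci"]), "loci;", len(results["panel"]), "panel SNPs on",
      results["panel"].n_loci_with_snps, "loci")
print(results["thresholds"].to_string())
pca = results["pca"]
print("PC1/PC2 variance explained: %.1f%% / %.1f%%"
      % tuple(100 * pca.variance_ratio[:2]))
print("population silhouette on PC1-2: %.2f" % pca.silhouette())
```

prints

```
58 loci; 34 panel SNPs on 25 loci
min_coverage
5     34
10    34
15    34
20    34
25    34
50    29
PC1/PC2 variance explained: 82.0% / 12.9%
population silhouette on PC1-2: 0.66
```

Reading: a 600 kb genome digested with the default rare cutter yields 58
fragment-end loci, 34 of which carry panel SNPs; every panel SNP is
genotypable at 25× in ≥ 75% of the four samples (the pipeline's coverage is
deep at this scale), and the two simulated populations separate cleanly on
the first principal component, which carries 82% of the fingerprint
variance. The silhouette (0.66 on the first two PCs) is the package's
separation score: above 0 means replicates sit closer to their own
population than to the other one. `demo_out/` holds the artifacts as
FASTA/TSV/VCF (consensus loci, panel, AF matrix, PCA scores, saturation
curve).

The same pipeline is scriptable from the shell:

```
gwaff run --config config.yaml --outdir out/
gwaff simulate|preprocess|assemble|map|panel|fingerprint|concordance|pca|saturate --help
```

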