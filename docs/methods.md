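# Methods

`gwaff` implements genome-wide allele frequency fingerprinting (GWAFF) of
pooled population samples from genotyping-by-sequencing (GBS) data, together
with a synthetic data generator that reproduces the statistical structure the
analysis relies on. This note documents the models, the parameter choices,
the numerical conventions, and the known limitations.

## The measurement model

A GBS library reduces a genome to the set of restriction fragments whose both
ends are cut sites and whose length survives size selection (100–1000 bp by
default). Single-end reads start at a cut site, so each sequenceable fragment
contributes two *loci* — one 64-mer per end after barcode removal and hard
trimming. A pooled sample (DNA from many individuals of one outbreeding
population) yields, at each bi-allelic site, reads that carry the alternate
allele with probability equal to the pool allele frequency. The fingerprint
of a sample is the vector of alternate-allele frequencies across a reference
SNP panel; populations are compared by PCA of their fingerprints.

## Pipeline stages and conventions

**Demultiplexing** assigns a read to the unique barcode whose sequence
exactly equals the read prefix; one mismatch anywhere in the barcode sends
the read to `unassigned`. The barcode set must be prefix-free, which makes
exact-prefix assignment unambiguous; the set constructor enforces this.
Barcode bases are stripped; cut-site remnant bases are genomic and retained.

**Filtering** applies, in fixed order: (1) hard trim to 64 bases (responding
to 3′ quality decay on older chemistry); (2) adapter clipping at the leftmost
exact occurrence (a prefix of the adapter suffices at the read end);
(3) removal of reads shorter than 64 bases; (4) removal of reads in which
fewer than 95% of bases reach Phred 15. Survivors are exactly 64 bases, so
the operation is idempotent. The quality rule at 64 bp means 61 good bases
pass (95.3%) and 60 fail (93.75%). The sample-size convention for read-count
statistics is the n−1 denominator; the coefficient of variation is SD/mean,
optionally recomputed after dropping a stated number of lowest-count samples.

**Assembly** groups identical reads into stacks; stacks with depth ≥ 3 are
primary. Primary stacks at Hamming distance ≤ 2 are connected, and loci are
the connected components of that graph — no component splitting, matching a
stacks-style assembler with repeat deleveraging off. The consensus is the
depth-weighted plurality base per position; ties resolve to the
lexicographically smallest base (A < C < G < T). Remaining (secondary) reads
join the unique nearest consensus within distance 4; ties and more distant
reads are dropped. All distances are substitution-only: reads are cut-site
anchored and equal length, so gaps cannot arise. Candidate stack pairs are
found by pigeonhole segmentation (three exact-match segments for distance
bound 2), which provably retrieves a superset of all qualifying pairs; the
test suite checks bit-identical agreement with an exhaustive all-pairs
oracle.

**Mapping** is ungapped end-to-end Hamming matching of 64-base reads against
consensus loci with at most 2 mismatches, keeping only unique best hits
(the classic `-v 2 -m 1` contract). Both orientations are searched; the two
orientations of one locus count as a single candidate, and the better
orientation is used. The segment index again guarantees linear-scan
equivalence (tested). Pileups count raw bases per (locus, offset);
reverse-orientation reads contribute complemented bases at mirrored offsets.

**SNP panel.** Equal numbers of quality-filtered reads from every population
are pooled (uniform sampling without replacement), mapped, and piled up. A
site is a bi-allelic SNP iff the top two bases each have ≥ 5 supporting
reads, every other base has < 5, and minor/(major+minor) ≥ the MAF threshold
(1% or 5%). The MAF denominator is the top-two-allele depth, consistent with
treating the site as bi-allelic; a third allele reaching 5 reads disqualifies
the site. Ranking ties resolve in A<C<G<T order. Descriptive outputs —
SNPs per read offset and SNPs per locus — mirror the standard panel QC
plots.

The equal-read pool should be sized so per-locus pooled depth lands in the
hundreds, the regime this calling rule is designed for. At very deep pools
(tens of thousands-fold per locus) sequencing-error bases alone exceed the
third-allele cap and the strict bi-allelic rule rejects clean sites; the
recovery experiment therefore pools 20k reads per population (~400–600× per
locus on the default genome), matching the operating point of real pooled
panels rather than the raw desk-scale read surplus.

**Fingerprints.** Per sample and panel site, coverage is ref+alt depth
(other bases ignored) and AF = alt/(ref+alt) when coverage ≥ 5, else
missing. Genotypability tables count sites with coverage ≥ t in at least
⌈0.75·n⌉ samples for t ∈ {5,10,15,20,25,50}. Replicate concordance bins
sites by coverage — (5≤X<10, 10≤X<20, X≥20), a site qualifying only if its
coverage falls in the bin in *every* replicate — samples 1000 sites per bin,
and reports the mean and SD of pairwise Pearson r (complete pairs, n−1
convention). PCA is column-centred without unit-variance scaling (allele
frequencies already share the [0,1] scale; a scaling switch is not offered
because it would re-weight low-information sites upward), restricted to
sites called in all samples; variance-explained fractions sum to one over
all components and scores are deterministic up to sign. Separation is
quantified as the mean silhouette of population labels on the first two
components — a declared proxy for visual separability; silhouette is
invariant to component sign flips. The panel-size curve subsamples
500–10,000 complete-case sites without replacement and recomputes the
silhouette.

**Saturation.** Budgets subsample reads uniformly without replacement
(reads are physical molecules). The full pool is mapped once and budget
subsets reuse the per-read assignments — per-read mapping does not depend on
other reads, so this is exactly equivalent to re-mapping each subsample.
Budgets are nested prefixes of one permutation, so each emitted curve is
monotone in budget by construction, as a physical sequencing run would be.
Cross-sample locus-coverage correlation is the Pearson matrix over per-locus
mapped depths, restricted to SNP-bearing loci (one row per locus).

## The synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions of the recovery experiments.

- **Genome**: i.i.d. bases at a requested GC fraction. Real genomes have
  repeats and compositional heterogeneity; see Limitations.
- **Enzymes**: IUPAC patterns with top-strand cut offsets, validated to be
  reverse-complement closed. Encoded as configuration; `GCWGC` (cut 1, one
  degenerate position, expected site rate 2/4⁵) and `CTGCAG` (cut 5, rate
  1/4⁶) ship as the frequent/rare defaults. Digestion is complete, with no
  methylation sensitivity — the same simplification the in-silico digestion
  of a reference genome makes.
- **Populations**: a polycross variety is a pool of founder haplotypes
  (default 24). Variant sites are placed i.i.d. at density 0.01/bp —
  conservative for a highly diverse outbreeding grass. Pool frequencies are
  Beta(0.8, 0.8) draws quantised to founder-count fractions (truncated away
  from 0 and 1 for a single population). Multiple populations share sites
  and diverge by the Balding–Nichols model with Fst = 0.05, a realistic
  between-variety value; per-population frequencies may hit 0 or 1.
- **Coverage non-uniformity**: fragment sampling weights are
  exp(N(0, σ)) · exp(−length/λ) with σ = 1.0 (per-locus lognormal
  efficiency) and λ = 300 bp (short-fragment amplification advantage),
  normalised. These two terms reproduce the strongly shared, right-skewed
  locus-coverage profile pooled GBS shows, including high cross-sample
  coverage correlation.
- **Reads**: a fragment is drawn by weight; either end is sequenced with
  equal probability, the far end as the reverse-complement strand; each
  covered variant site emits the alternate allele independently with
  probability `true_af` (infinite-template pool sampling); the read is
  barcode + genomic bases truncated to 101; substitution errors hit
  post-barcode bases i.i.d. at 0.2%; barcode bases are error-free so
  demultiplexing truth is exact. A finite-pool mode (`resample_pool`) first
  draws a finite set of haplotypes with replacement, reproducing the
  seedling-sampling variance that distinguishes sampling replicates.
- **Qualities**: constant Phred 30, with a configurable fraction (default
  2%) of reads whose per-base scores are uniform on [2, 14] and therefore
  fail the 95%/Q15 rule — a synthetic quality model; no empirical error
  profile is emulated.
- **Barcodes**: random, distinct, prefix-free, lengths cycling 4–8 so the
  cut-site remnant is phase-staggered across sequencing cycles. Optional
  lognormal per-barcode efficiencies (σ = 0.3) reproduce a per-sample
  read-count CV around 0.3, the unevenness level multiplexed GBS lanes
  show.
- **Seeds**: every stochastic operation takes an explicit integer seed;
  pipeline stages derive seeds deterministically from one global seed and
  the stage name, so whole runs are bit-reproducible.

## Recovery experiments and their oracles

`gwaff.experiments` packages the seeded study-scale analyses; the same
functions drive the test suite and `scripts/acceptance.py`.

**Allele-frequency recovery** simulates 2 populations × 4 sampling
replicates on a 1 Mb rare-cutter genome (≈50 sequenceable fragments ≈100
loci), 200k reads per sample, runs the full pipeline, matches assembled loci
back to fragment-end templates, and scores AF calls against the generating
pool frequencies. Because full-depth locus coverage is ~2000×, the low
coverage bins are populated by sweeping sequencing budgets (1k–200k reads
per sample, reusing the full-depth mapping) and pooling (coverage, error)
cells across budgets. RMSE per coverage bin follows c^(−1/2) while read
sampling dominates; the power-law fit is restricted to bins up to ~600×,
beyond which a small systematic floor flattens the curve. The mean bias is
reported with a site-clustered standard error — cells at one site share the
true frequency and any systematic loss, so the per-cell SE would overstate
precision.

A reproducible finding of this experiment: under 0.2% sequencing error the
AF estimator is *not* exactly unbiased — the measured mean bias is ≈ −0.003
to −0.006. The cause is differential read loss at the mismatch bound: a read
carrying the minor allele lies one mismatch closer to the `-v 2` limit than
a major-allele read, so sequencing errors push it over the bound more often,
and on loci carrying several SNPs a read with multiple minor alleles can
exceed the bound outright. With the error rate set to zero the measured bias
is −0.0004 ± 0.0008, i.e. statistically zero — the loss is a property of
bounded-mismatch mapping itself, not of the frequency estimator. At the
experiment's precision (site-clustered SE ≈ 0.001) this bias is detectable
at roughly 2–4 standard errors depending on seed; the corresponding
acceptance test asserts unbiasedness at 3 SEs and is expected to fail for
some seeds — that failure documents a real, explained property of the
method rather than a defect of the implementation.

**Concordance attenuation** uses the site-level generator (exact known
coverage): replicate AFs are Binomial(c, p)/c draws at fixed c = 7, 14, 40,
one coverage per bin, with p from the quantised Beta prior. The
between-replicate Pearson r must match the attenuation closed form
Var(p) / (Var(p) + E[p(1−p)]/c) and increase strictly across bins.

**Poisson occupancy** switches off both weight terms and sequencing error so
reads spread uniformly over L loci; the number of loci at depth ≥ c under
budget b is compared with L·P(Poisson(b/L) ≥ c) within 3 SDs of the implied
binomial count distribution.

**Cutter crossover** digests one 400 kb genome with both enzymes: the rare
cutter (≈38 loci) leads at a 500-read budget, the frequent cutter (≈1000
loci) overtakes by 60k reads at 5× — the canonical budget trade-off between
enzymes.

**Discrimination** builds 8 Balding–Nichols populations × 4 replicates over
12,000 sites read at coverage 5 + Poisson(10) per cell (complete case by
construction) and checks that every population clusters (positive
silhouette) and that the seed-averaged silhouette-vs-panel-size curve rises
from 500 to 10,000 sites. Near its plateau the averaged curve can wiggle at
the between-round noise scale, so monotonicity is asserted allowing
deviations within two standard errors of each step (and end-to-end
increase strictly).

## Problem sizes

The recovery experiment runs 1.6M reads through the full pipeline in well
under a minute on one core; generation, demultiplexing, stacking and mapping
are all vectorised over uint8 code matrices, with row-uniquing via packed
64-bit keys and candidate retrieval via pigeonhole segment hashing. The
site-level experiments are effectively instant. These sizes were chosen as
the smallest at which the statistical checks have useful power.

## Known limitations

- The genome model has no repeats; real GBS suffers ambiguous-mapping
  losses at repeat-derived loci far beyond what i.i.d. genomes produce.
- Within-read variant draws are independent across sites (linkage
  equilibrium at 64 bp scale); real pools have within-fragment LD, which
  changes the joint distribution of multi-SNP reads (the marginal per-site
  frequencies are unaffected).
- No indels, no PCR duplicates, no paired ends, no methylation-sensitive
  digestion, no empirical quality profiles, no barcode sequencing errors.
- Allele-frequency calls ignore base qualities (the `-v`-style mapper does
  not weight mismatches by quality either).
- Passing tests demonstrate correct recovery of the generator's structure;
  they do not certify performance on real data with the artefacts above.
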