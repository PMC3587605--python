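import re

import numpy as np
import pytest
import gwaff
from gwaff import simulate as sim
from gwaff._seq import encode


class TestGenome:
    def test_seed_determinism(self):
        a = gwaff.generate_genome(1000, 0.5, seed=7)
        b = gwaff.generate_genome(1000, 0.5, seed=7)
        assert a.sequence == b.sequence

    def test_gc_content_within_binomial_ci(self):
        g = gwaff.generate_genome(10**6, 0.5, seed=1)
        gc = sum(g.sequence.count(b) for b in "GC")
        sd = np.sqrt(10**6 * 0.25)
        assert abs(gc - 5e5) < 3 * sd

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-3, 0.5),
                                           (100, 0.0), (100, 1.0)])
    def test_invalid_arguments(self, length, gc):
        with pytest.raises(ValueError):
            gwaff.generate_genome(length, gc)


class TestEnzymes:
    def test_known_enzymes_validate(self):
        assert gwaff.PSTI.recognition == "CTGCAG"
        assert gwaff.APEKI.site_probability == pytest.approx(2 / 4**5)

    def test_non_palindromic_rejected(self):
        with pytest.raises(ValueError):
            sim.Enzyme("bad", "ACGTA", 1)

    def test_short_pattern_rejected(self):
        with pytest.raises(ValueError):
            sim.Enzyme("bad", "AT", 1)

    def test_cut_offset_bounds(self):
        with pytest.raises(ValueError):
            sim.Enzyme("bad", "CTGCAG", 7)


class TestDigest:
    def test_no_site_single_uncut_fragment(self):
        frags = gwaff.digest("A" * 50, gwaff.PSTI)
        assert len(frags) == 1
        assert not frags[0].left_cut and not frags[0].right_cut
        assert frags[0].sequence == "A" * 50

    def test_pst1_hand_counted_internal_fragment(self):
        # cut sites start at 5 and 111; cut offset 5 -> cuts at 10 and 116
        seq = "AAAAA" + "CTGCAG" + "T" * 100 + "CTGCAG" + "AAAAA"
        frags = gwaff.digest(seq, gwaff.PSTI)
        assert [len(f) for f in frags] == [10, 106, len(seq) - 116]
        internal = frags[1]
        assert internal.left_cut and internal.right_cut
        assert internal.sequence.startswith("G")  # cut remnant retained

    def test_apeki_wobble_expansion(self):
        for core, cuts in [("GCAGC", True), ("GCTGC", True),
                           ("GCCGC", False)]:
            frags = gwaff.digest("T" * 20 + core + "T" * 20, gwaff.APEKI)
            assert (len(frags) == 2) == cuts

    def test_regex_scan_oracle(self):
        rng = np.random.default_rng(5)
        g = gwaff.generate_genome(20_000, 0.5, seed=int(rng.integers(1e6)))
        for enzyme, pattern in [(gwaff.PSTI, "CTGCAG"),
                                (gwaff.APEKI, "GC[AT]GC")]:
            expected = {m.start() + enzyme.cut_offset
                        for m in re.finditer(f"(?={pattern})", g.sequence)}
            cuts = sim.find_cut_positions(encode(g.sequence), enzyme)
            assert set(cuts.tolist()) == expected

    def test_fragments_partition_sequence(self):
        g = gwaff.generate_genome(50_000, 0.4, seed=3)
        frags = gwaff.digest(g, gwaff.APEKI)
        assert sum(len(f) for f in frags) == g.length
        assert "".join(f.sequence for f in frags) == g.sequence

    def test_digest_idempotent_on_internal_fragments(self):
        g = gwaff.generate_genome(200_000, 0.5, seed=9)
        frags = gwaff.select_fragments(gwaff.digest(g, gwaff.PSTI))
        for f in frags[:10]:
            # strip the flanking remnants that reconstitute the site
            inner = f.sequence[len(gwaff.PSTI.recognition):]
            refrag = gwaff.digest(inner, gwaff.PSTI)
            assert len(refrag) == 1

    def test_site_counts_near_motif_probability(self):
        g = gwaff.generate_genome(10**6, 0.5, seed=2)
        for enzyme in (gwaff.PSTI, gwaff.APEKI):
            n = len(sim.find_cut_positions(encode(g.sequence), enzyme))
            lam = g.length * enzyme.site_probability
            assert abs(n - lam) < 3 * np.sqrt(lam)


class TestSelectFragments:
    def _frag(self, length, left=True, right=True):
        return sim.Fragment(0, length, left, right, "A" * length)

    def test_length_boundaries_inclusive(self):
        frags = [self._frag(99), self._frag(100), self._frag(1000),
                 self._frag(1001)]
        kept = gwaff.select_fragments(frags, 100, 1000)
        assert [len(f) for f in kept] == [100, 1000]

    def test_terminal_fragment_excluded(self):
        assert gwaff.select_fragments([self._frag(500, right=False)]) == []

    def test_bad_window(self):
        with pytest.raises(ValueError):
            gwaff.select_fragments([], 10, 5)


class TestPopulations:
    def test_true_af_equals_haplotype_mean(self):
        g = gwaff.generate_genome(50_000, 0.5, seed=1)
        pop = gwaff.make_population(g, n_founders=20, seed=2)
        assert np.allclose(pop.true_af, pop.founder_haplotypes.mean(axis=0))
        assert ((pop.true_af > 0) & (pop.true_af < 1)).all()

    def test_counting_ten_alt_of_forty_haplotypes(self):
        sites = np.zeros(1, dtype=sim._SITE_DTYPE)
        hap = np.zeros((40, 1), dtype=np.uint8)
        hap[:10, 0] = 1
        pop = sim.PopulationModel("p", 40, sites, hap)
        assert pop.true_af[0] == 0.25

    def test_no_alt_carriers_means_af_zero(self):
        sites = np.zeros(1, dtype=sim._SITE_DTYPE)
        pop = sim.PopulationModel("p", 8, sites, np.zeros((8, 1), np.uint8))
        assert pop.true_af[0] == 0.0

    def test_too_few_founders(self):
        g = gwaff.generate_genome(1000, 0.5, seed=1)
        with pytest.raises(ValueError):
            gwaff.make_population(g, n_founders=1)

    def test_balding_nichols_quantized_and_bounded(self):
        af = sim.balding_nichols_af(4, 500, fst=0.1, rng=3, n_founders=24)
        assert af.shape == (4, 500)
        assert ((af >= 0) & (af <= 1)).all()
        assert np.allclose(af * 24, np.rint(af * 24))

    def test_resample_pool_changes_frequencies(self):
        g = gwaff.generate_genome(50_000, 0.5, seed=1)
        pop = gwaff.make_population(g, n_founders=24, seed=2)
        sub = sim.resample_pool(pop, 200, seed=3)
        assert sub.n_sites == pop.n_sites
        assert np.allclose(sub.true_af, sub.founder_haplotypes.mean(axis=0))
        assert not np.allclose(sub.true_af, pop.true_af)


class TestFragmentWeights:
    def test_length_bias_closed_form(self):
        frags = [sim.Fragment(0, 100, True, True, "A" * 100),
                 sim.Fragment(100, 1100, True, True, "A" * 1000)]
        cfg = sim.SimConfig(locus_lognormal_sigma=0.0, length_bias_scale=300)
        w = sim.assign_fragment_weights(frags, cfg, seed=0)
        assert w[0] / w[1] == pytest.approx(np.exp(900 / 300))

    def test_degenerate_limit_is_uniform(self):
        frags = [sim.Fragment(i * 500, i * 500 + 100 + 50 * i, True, True,
                              "A" * (100 + 50 * i)) for i in range(4)]
        cfg = sim.SimConfig(locus_lognormal_sigma=0.0,
                            length_bias_scale=np.inf)
        w = sim.assign_fragment_weights(frags, cfg, seed=0)
        assert np.allclose(w, 0.25)

    def test_empty_fragment_list(self):
        with pytest.raises(ValueError):
            sim.assign_fragment_weights([], sim.SimConfig(), 0)

    def test_length_rank_shared_between_seeds(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(1)
        frags = [sim.Fragment(0, n, True, True, "A" * n)
                 for n in rng.integers(100, 1000, 40)]
        cfg = sim.SimConfig(locus_lognormal_sigma=0.5)
        w1 = sim.assign_fragment_weights(frags, cfg, seed=1)
        w2 = sim.assign_fragment_weights(frags, cfg, seed=2)
        rho = spearmanr(w1, w2).statistic
        assert 0.2 < rho < 1.0  # shared length component, distinct noise


class TestGenerateReads:
    def _single_fragment_world(self, af, seed=0):
        g = gwaff.generate_genome(400, 0.5, seed=8)
        frag = sim.Fragment(0, 400, True, True, g.sequence)
        sites = np.zeros(1, dtype=sim._SITE_DTYPE)
        sites["pos"] = 30
        sites["ref"] = encode(g.sequence)[30]
        sites["alt"] = (sites["ref"] + 1) % 4
        n_alt = int(round(af * 20))
        hap = np.zeros((20, 1), np.uint8)
        hap[:n_alt, 0] = 1
        pop = sim.PopulationModel("p", 20, sites, hap)
        return pop, [frag]

    def test_fixed_alt_always_emitted(self):
        pop, frags = self._single_fragment_world(1.0)
        cfg = sim.SimConfig(substitution_error_rate=0.0,
                            low_quality_fraction=0.0)
        reads = gwaff.generate_reads(pop, frags, np.ones(1), "ACGT", 500,
                                     cfg, seed=1)
        # identify forward-end reads by their first genomic bases (error
        # free, no variants before the site at position 30)
        prefix = encode(frags[0].sequence[:11])
        fwd = (reads.seqs[:, 4:15] == prefix).all(axis=1)
        assert fwd.any() and (~fwd).any()
        alt = pop.variant_sites["alt"][0]
        assert (reads.seqs[fwd, 4 + 30] == alt).all()

    def test_alt_fraction_binomial(self):
        pop, frags = self._single_fragment_world(0.3)
        cfg = sim.SimConfig(substitution_error_rate=0.0,
                            low_quality_fraction=0.0)
        reads = gwaff.generate_reads(pop, frags, np.ones(1), "ACGT", 20_000,
                                     cfg, seed=2)
        alt = pop.variant_sites["alt"][0]
        ref = pop.variant_sites["ref"][0]
        col = reads.seqs[:, 34]
        n_alt, n_ref = int((col == alt).sum()), int((col == ref).sum())
        n = n_alt + n_ref
        assert n > 5000
        assert abs(n_alt / n - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_zero_reads(self):
        pop, frags = self._single_fragment_world(0.5)
        reads = gwaff.generate_reads(pop, frags, np.ones(1), "ACGT", 0,
                                     sim.SimConfig(), seed=1)
        assert len(reads) == 0

    def test_deterministic_given_seed(self):
        pop, frags = self._single_fragment_world(0.5)
        a = gwaff.generate_reads(pop, frags, np.ones(1), "ACGT", 200,
                                 sim.SimConfig(), seed=9)
        b = gwaff.generate_reads(pop, frags, np.ones(1), "ACGT", 200,
                                 sim.SimConfig(), seed=9)
        assert (a.seqs == b.seqs).all() and (a.quals == b.quals).all()

    def test_reads_start_with_barcode(self):
        pop, frags = self._single_fragment_world(0.5)
        reads = gwaff.generate_reads(pop, frags, np.ones(1), "TTGCA", 50,
                                     sim.SimConfig(), seed=3)
        assert (reads.seqs[:, :5] == encode("TTGCA")).all()
        assert reads.width == 101

    def test_low_quality_fraction_fails_filter(self):
        pop, frags = self._single_fragment_world(0.5)
        cfg = sim.SimConfig(low_quality_fraction=0.5)
        reads = gwaff.generate_reads(pop, frags, np.ones(1), "ACGT", 2000,
                                     cfg, seed=4)
        frac_low = (reads.quals.max(axis=1) < 15).mean()
        assert abs(frac_low - 0.5) < 3 * np.sqrt(0.25 / 2000)


class TestBarcodes:
    def test_thirty_two_prefix_free_barcodes(self):
        bcs = sim.make_barcode_set(32, (4, 8), seed=0)
        assert len(bcs) == 32
        seqs = bcs.sequences
        assert len(set(seqs)) == 32
        for a in seqs:
            for b in seqs:
                if a != b:
                    assert not b.startswith(a)
        assert {len(s) for s in seqs} == {4, 5, 6, 7, 8}

    def test_prefix_conflict_rejected_by_container(self):
        with pytest.raises(ValueError):
            sim.BarcodeSet([("ACGT", 1.0), ("ACGTA", 1.0)])

    def test_impossible_set_raises(self):
        with pytest.raises(ValueError):
            sim.make_barcode_set(300, (4, 4), seed=0)

    def test_efficiency_weights_positive(self):
        bcs = sim.make_barcode_set(16, (4, 8), seed=1, efficiency_sigma=0.3)
        assert (bcs.weights > 0).all()
        assert bcs.weights.std() > 0


class TestTruthBookkeeping:
    def test_truth_loci_match_consensus(self, mini_world, mini_loci):
        truth = sim.build_truth_loci(mini_world["fragments"],
                                     mini_world["populations"])
        match = sim.match_loci_to_truth(mini_loci.consensus, truth)
        assert (match >= 0).all()
        # consensus may differ from the genome template only at variant
        # sites (where the pooled-majority allele can be the alternate)
        for i, t in enumerate(match):
            diff = np.flatnonzero(mini_loci.consensus[i]
                                  != truth[t].template)
            assert set(diff.tolist()) <= set(truth[t].sites)
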