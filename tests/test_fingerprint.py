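import numpy as np
import pandas as pd
import pytest

from gwaff import fingerprint as fp
from gwaff.panel import SNPPanel


def make_panel(sites):
    df = pd.DataFrame(sites, columns=["locus_id", "offset", "ref", "alt",
                                      "pool_maf", "pool_depth"])
    return SNPPanel(df, 0.05, 5)


def make_matrix(af, cov, populations, min_cov=5):
    af = np.asarray(af, dtype=float)
    cov = np.asarray(cov)
    names = [f"{p}_r{i}" for i, p in enumerate(populations)]
    cols = pd.Index([f"S{j}" for j in range(af.shape[1])], name="site")
    af = np.where(cov >= min_cov, af, np.nan)
    samples = pd.DataFrame({"sample": names, "population": populations,
                            "replicate": range(len(names))})
    return fp.AFMatrix(pd.DataFrame(af, index=names, columns=cols),
                       pd.DataFrame(cov, index=names, columns=cols),
                       samples, min_cov)


class TestCallSampleAF:
    def _pileup(self, counts):
        pileup = np.zeros((1, 64, 4), dtype=np.int64)
        pileup[0, 0] = counts
        return pileup

    def test_af_and_coverage_arithmetic(self):
        panel = make_panel([(0, 0, "A", "C", 0.4, 20)])
        row = fp.call_sample_af(self._pileup((12, 8, 0, 0)), panel, 5)
        assert row["cov"].iloc[0] == 20
        assert row["af"].iloc[0] == pytest.approx(0.4)

    def test_below_min_cov_missing(self):
        panel = make_panel([(0, 0, "A", "C", 0.4, 20)])
        row = fp.call_sample_af(self._pileup((3, 1, 0, 0)), panel, 5)
        assert row["cov"].iloc[0] == 4
        assert np.isnan(row["af"].iloc[0])

    def test_fixed_reference_gives_zero(self):
        panel = make_panel([(0, 0, "A", "C", 0.4, 20)])
        row = fp.call_sample_af(self._pileup((10, 0, 0, 0)), panel, 5)
        assert row["af"].iloc[0] == 0.0

    def test_third_bases_ignored(self):
        panel = make_panel([(0, 0, "A", "C", 0.4, 20)])
        row = fp.call_sample_af(self._pileup((12, 8, 3, 2)), panel, 5)
        assert row["cov"].iloc[0] == 20

    def test_panel_locus_out_of_range(self):
        panel = make_panel([(5, 0, "A", "C", 0.4, 20)])
        with pytest.raises(ValueError):
            fp.call_sample_af(self._pileup((1, 1, 0, 0)), panel, 5)


class TestAFMatrix:
    def test_missingness_must_match_threshold(self):
        af = pd.DataFrame([[0.5, 0.2]], index=["s"],
                          columns=pd.Index(["S0", "S1"], name="site"))
        cov = pd.DataFrame([[10, 2]], index=["s"], columns=af.columns)
        samples = pd.DataFrame({"sample": ["s"], "population": ["p"],
                                "replicate": [1]})
        with pytest.raises(ValueError):
            fp.AFMatrix(af, cov, samples, min_cov=5)

    def test_lowering_min_cov_never_creates_missing(self):
        rng = np.random.default_rng(0)
        cov = rng.integers(0, 30, (4, 50))
        af = rng.random((4, 50))
        strict = make_matrix(af, cov, ["p"] * 4, min_cov=10)
        loose = make_matrix(af, cov, ["p"] * 4, min_cov=5)
        present_strict = ~strict.af.isna()
        present_loose = ~loose.af.isna()
        assert (present_loose | ~present_strict).all().all()


class TestGenotypedAtThresholds:
    def test_toy_hand_counts(self):
        # 4 samples; sites: always deep / deep in 3 of 4 / deep in 2 of 4
        cov = np.array([[60, 60, 4], [60, 7, 4], [60, 9, 60], [60, 2, 60]])
        m = make_matrix(np.full((4, 3), 0.5), cov, ["p"] * 4)
        counts = fp.genotyped_at_thresholds(m, thresholds=(5, 10, 50))
        # need ceil(0.75*4)=3 samples
        assert counts.loc[5] == 2   # site0 and site1 (cov>=5 in 3 samples)
        assert counts.loc[10] == 1  # only site0
        assert counts.loc[50] == 1
        assert (counts.diff().dropna() <= 0).all()

    def test_boundary_exactly_three_quarters(self):
        cov = np.vstack([np.full((24, 1), 10), np.full((8, 1), 1)])
        m = make_matrix(np.full((32, 1), 0.5), cov, ["p"] * 32)
        assert fp.genotyped_at_thresholds(m, thresholds=(5,)).loc[5] == 1


class TestReplicateConcordance:
    def test_identical_replicates_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        af = np.tile(rng.random(200), (4, 1))
        m = make_matrix(af, np.full((4, 200), 8), ["p"] * 4)
        table = fp.replicate_concordance(m, bins=((5, 10),), n_per_bin=100,
                                         seed=0)
        assert table.mean_r.iloc[0] == pytest.approx(1.0)
        assert table.n_pairs.iloc[0] == 6

    def test_bin_requires_all_replicates_inside(self):
        cov = np.array([[8, 8], [8, 8], [8, 25], [8, 8]])
        m = make_matrix(np.full((4, 2), 0.5), cov, ["p"] * 4)
        table = fp.replicate_concordance(m, bins=((5, 10),), n_per_bin=1,
                                         seed=0)
        assert table.n_sites.iloc[0] == 1  # second site disqualified

    def test_no_qualifying_sites_raises(self):
        m = make_matrix(np.full((4, 3), 0.5), np.full((4, 3), 50), ["p"] * 4)
        with pytest.raises(ValueError):
            fp.replicate_concordance(m, bins=((5, 10),), n_per_bin=1, seed=0)

    def test_allow_fewer_accepts_small_bins(self):
        m = make_matrix(np.full((4, 3), 0.5), np.full((4, 3), 8), ["p"] * 4)
        table = fp.replicate_concordance(m, bins=((5, 10),), n_per_bin=100,
                                         seed=0, allow_fewer=True)
        assert table.n_sites.iloc[0] == 3

    def test_attenuation_closed_form(self):
        rng = np.random.default_rng(2)
        p = rng.beta(0.8, 0.8, 3000).clip(1 / 24, 23 / 24)
        m = fp.simulate_af_matrix(p, 12, 4, seed=3)
        table = fp.replicate_concordance(m, bins=((10, 20),), n_per_bin=3000,
                                         seed=0)
        oracle = fp.concordance_attenuation(p, 12)
        se = table.sd_r.iloc[0] / np.sqrt(table.n_pairs.iloc[0])
        assert abs(table.mean_r.iloc[0] - oracle) < max(3 * se, 0.02)


class TestPCA:
    def _separable_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.random(400)
        af = []
        for pop_shift in (0.0, 0.35):
            profile = np.clip(base + pop_shift, 0, 1)
            for _ in range(4):
                af.append(np.clip(profile + rng.normal(0, 0.02, 400), 0, 1))
        return make_matrix(af, np.full((8, 400), 30),
                           ["a"] * 4 + ["b"] * 4)

    def test_separable_populations_cluster(self):
        res = fp.pca_fingerprint(self._separable_matrix())
        scores = res.scores.to_numpy()[:, :2]
        within = max(np.linalg.norm(scores[i] - scores[j])
                     for i in range(4) for j in range(4) if i != j)
        between = min(np.linalg.norm(scores[i] - scores[j])
                      for i in range(4) for j in range(4, 8))
        assert between > within
        assert res.silhouette() > 0.5

    def test_variance_fractions_sum_to_one(self):
        res = fp.pca_fingerprint(self._separable_matrix())
        assert res.variance_ratio.sum() == pytest.approx(1.0)

    def test_constant_column_contributes_nothing(self):
        m = self._separable_matrix()
        af2 = m.af.copy()
        af2["S_const"] = 0.4
        cov2 = m.cov.copy()
        cov2["S_const"] = 30
        m2 = fp.AFMatrix(af2, cov2, m.samples, m.min_cov)
        a = fp.pca_fingerprint(m)
        b = fp.pca_fingerprint(m2)
        assert np.allclose(np.abs(a.scores.to_numpy()),
                           np.abs(b.scores.to_numpy()), atol=1e-8)

    def test_silhouette_invariant_to_sign_flips(self):
        res = fp.pca_fingerprint(self._separable_matrix())
        flipped = res.scores.copy()
        flipped.iloc[:, 0] *= -1
        alt = fp.PCAResult(flipped, res.variance_ratio, res.n_sites,
                           res.samples)
        assert alt.silhouette() == pytest.approx(res.silhouette())

    def test_no_complete_sites_raises(self):
        cov = np.array([[4, 10], [10, 4]])
        m = make_matrix([[0.1, 0.2], [0.3, 0.4]], cov, ["a", "b"])
        with pytest.raises(ValueError):
            fp.pca_fingerprint(m)


class TestSubsampleSeparation:
    def test_full_panel_matches_direct_pca(self):
        rng = np.random.default_rng(3)
        m = TestPCA()._separable_matrix(seed=3)
        curve = fp.snp_subsample_separation(m, n_sites_list=(400,), seed=0)
        assert curve.silhouette.iloc[0] == pytest.approx(
            fp.pca_fingerprint(m).silhouette())

    def test_requesting_too_many_sites(self):
        m = TestPCA()._separable_matrix()
        with pytest.raises(ValueError):
            fp.snp_subsample_separation(m, n_sites_list=(401,), seed=0)


class TestAccuracyHelpers:
    def test_simulate_af_matrix_marginals(self):
        p = np.full(4000, 0.3)
        m = fp.simulate_af_matrix(p, 25, 2, seed=4)
        mean = m.af.to_numpy().mean()
        assert abs(mean - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 25 / 8000)

    def test_rmse_scales_as_inverse_sqrt_coverage(self):
        rng = np.random.default_rng(5)
        p = rng.beta(0.8, 0.8, 2000).clip(1 / 24, 23 / 24)
        af, cov, truth = [], [], []
        for c in (8, 16, 32, 64, 128):
            m = fp.simulate_af_matrix(p, c, 2, seed=c)
            af.append(m.af.to_numpy().ravel())
            cov.append(m.cov.to_numpy().ravel())
            truth.append(np.tile(p, 2))
        acc = fp.af_accuracy(np.concatenate(af), np.concatenate(cov),
                             np.concatenate(truth),
                             bin_edges=(5, 10, 20, 40, 80, 160))
        slope = fp.rmse_loglog_slope(acc)
        assert slope == pytest.approx(-0.5, abs=0.06)
        assert (acc.sort_values("mean_cov").rmse.diff().dropna() < 0).all()
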