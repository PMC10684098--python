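"""RINT, variant QC, additive/dominance association, meta-analysis, PGS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vitdgwas as vg
from vitdgwas.simdata import GenotypeMatrix


def _geno(values):
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    variants = pd.DataFrame({"chrom": 1, "id": [f"v{i}" for i in range(m)],
                             "pos": np.arange(1, m + 1) * 1000,
                             "a1": "A", "a2": "G"})
    samples = pd.DataFrame({"iid": [f"s{i}" for i in range(n)],
                            "ancestry": "X"})
    return GenotypeMatrix(values=values, variants=variants, samples=samples)


def _sim(n=2000, m=100, seed=51, **kw):
    cfg = vg.SimConfig(n_per_ancestry={"A": n}, m_variants=m,
                       fst={"A": 0.0}, ld_block_size=10, seed=seed, **kw)
    freqs = vg.simulate_frequencies(cfg)
    return vg.simulate_genotypes(freqs, cfg)


class TestRint:
    def test_monotone_in_input_order(self, rng):
        x = rng.standard_normal(200)
        out = vg.rint(x)
        assert np.array_equal(np.argsort(x), np.argsort(out))

    def test_middle_of_three_maps_to_zero(self):
        out = vg.rint([5.0, 1.0, 9.0])
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_moments_near_standard_normal(self, rng):
        out = vg.rint(rng.exponential(size=10_000))
        assert abs(out.mean()) < 0.02
        assert out.var() == pytest.approx(1.0, rel=0.02)

    def test_missing_preserved_and_ties_averaged(self):
        out = vg.rint([1.0, np.nan, 2.0, 2.0, 3.0])
        assert np.isnan(out[1])
        assert out[2] == out[3]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            vg.rint([2.0, 2.0, 2.0])


class TestVariantQC:
    def test_monomorphic_fails_maf(self):
        geno = _geno(np.column_stack([np.zeros(100, dtype=int),
                                      np.random.default_rng(1).integers(0, 3, 100)]))
        keep, report = vg.variant_qc(geno, maf_min=0.01)
        assert not keep[0]

    def test_all_heterozygotes_fail_hwe(self):
        geno = _geno(np.column_stack([np.ones(1000, dtype=int)]))
        keep, report = vg.variant_qc(geno, maf_min=0.01)
        # observed (0, 1000, 0) vs expected (250, 500, 250): chi2 = 1000
        assert report["hwe_p"].iloc[0] < 1e-6
        assert not keep[0]

    def test_mac_is_maf_times_2n(self):
        rng = np.random.default_rng(2)
        geno = _geno(rng.binomial(2, 0.002, size=(500, 1)))
        keep, report = vg.variant_qc(geno, maf_min=0.0, n_smallest=2279)
        expected = report["maf"].iloc[0] * 2 * 2279
        assert report["mac"].iloc[0] == pytest.approx(expected)
        # the headline arithmetic: MAF 0.002 in N = 2,279 gives MAC ~ 9.1
        assert 0.002 * 2 * 2279 == pytest.approx(9.116)


class TestAdditiveGwas:
    def test_type_one_error_calibrated(self):
        geno = _sim(n=1500, m=1000, seed=52)
        y = np.random.default_rng(9152).standard_normal(1500)
        rec = vg.additive_gwas(y, geno)
        frac = (rec["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.014)

    def test_planted_qtl_recovered(self):
        beta = np.sqrt(0.01 / (2 * 0.3 * 0.7))
        geno = _sim(n=5000, m=50, seed=53)
        rng = np.random.default_rng(9153)
        x = geno.values[:, 7].astype(float)
        y = beta * x + rng.standard_normal(5000)
        rec = vg.additive_gwas(y, geno)
        row = rec.iloc[7]
        assert abs(row["beta"] - beta) < 2 * row["se"]
        assert rec["p"].idxmin() == 7

    def test_ols_equals_bruteforce_multiple_regression(self):
        geno = _sim(n=400, m=20, seed=54)
        rng = np.random.default_rng(9154)
        cov = rng.standard_normal((400, 3))
        y = cov @ [0.2, -0.1, 0.3] + rng.standard_normal(400)
        rec = vg.additive_gwas(y, geno, covariates=cov)
        for j in [0, 5, 19]:
            x = np.column_stack([np.ones(400), geno.values[:, j], cov])
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ coef
            s2 = r @ r / (400 - x.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
            assert rec["beta"].iloc[j] == pytest.approx(coef[1], abs=1e-10)
            assert rec["se"].iloc[j] == pytest.approx(se, abs=1e-10)

    def test_gls_with_identity_grm_equals_ols(self):
        geno = _sim(n=300, m=30, seed=55)
        y = np.random.default_rng(9155).standard_normal(300)
        grm = vg.GRM(values=np.eye(300), n_snps=30,
                     ids=geno.samples["iid"].to_numpy())
        ols = vg.additive_gwas(y, geno, mode="ols")
        gls = vg.additive_gwas(y, geno, mode="gls", grm=grm)
        assert np.abs(ols["beta"] - gls["beta"]).max() < 1e-10
        assert np.abs(ols["se"] - gls["se"]).max() < 1e-10

    def test_allele_flip_negates_beta(self):
        geno = _sim(n=500, m=10, seed=56)
        y = np.random.default_rng(9156).standard_normal(500)
        flipped = GenotypeMatrix(
            values=(2 - geno.values).astype(np.int8),
            variants=geno.variants.rename(columns={"a1": "a2", "a2": "a1"}),
            samples=geno.samples)
        r1 = vg.additive_gwas(y, geno)
        r2 = vg.additive_gwas(y, flipped)
        assert np.allclose(r1["beta"], -r2["beta"])
        assert np.allclose(r1["freq"], 1 - r2["freq"])
        assert np.allclose(r1["p"], r2["p"])

    def test_collinear_covariates_named(self):
        geno = _sim(n=100, m=10, seed=57)
        y = np.zeros(100)
        cov = np.ones((100, 2))
        with pytest.raises(ValueError, match="collinear"):
            vg.additive_gwas(y, geno, covariates=cov)


class TestDominanceGwas:
    def test_wald_matches_bruteforce_joint_ols(self):
        geno = _sim(n=1000, m=20, seed=58)
        y = np.random.default_rng(9158).standard_normal(1000)
        rec = vg.dominance_gwas(y, geno)
        for j in [0, 10]:
            xa = geno.values[:, j].astype(float)
            xd = (xa == 1).astype(float)
            x = np.column_stack([np.ones(1000), xa, xd])
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ coef
            s2 = r @ r / (1000 - 3)
            se_d = np.sqrt(s2 * np.linalg.inv(x.T @ x)[2, 2])
            chi2 = (coef[2] / se_d) ** 2
            assert rec["chi2"].iloc[j] == pytest.approx(chi2, abs=1e-8)
            assert rec["beta"].iloc[j] == pytest.approx(coef[2], abs=1e-10)

    def test_null_p_uniform_under_additive_only(self):
        geno = _sim(n=2000, m=800, seed=59)
        rng = np.random.default_rng(9159)
        # purely additive polygenic signal; dominance tests stay null
        d = geno.values.astype(float)
        y = d @ rng.standard_normal(800) * 0.01 + rng.standard_normal(2000)
        rec = vg.dominance_gwas(y, geno)
        ks = stats.kstest(rec["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_heterozygote_advantage_detected(self):
        geno = _sim(n=8000, m=10, seed=60)
        rng = np.random.default_rng(9160)
        xd = (geno.values[:, 4] == 1).astype(float)
        y = 0.3 * xd + rng.standard_normal(8000)
        rec = vg.dominance_gwas(y, geno)
        assert rec["p"].iloc[4] < 5e-8
        assert abs(rec["beta"].iloc[4] - 0.3) < 2 * rec["se"].iloc[4]

    def test_no_heterozygotes_flagged(self):
        vals = np.column_stack([np.repeat([0, 2], 50),
                                np.random.default_rng(3).integers(0, 3, 100)])
        rec = vg.dominance_gwas(np.zeros(100), _geno(vals))
        assert rec["inestimable"].iloc[0]
        assert np.isnan(rec["beta"].iloc[0])


class TestMetaIVW:
    def _records(self, betas, ses, ids=None):
        m = len(betas)
        ids = ids or [f"v{i}" for i in range(m)]
        return pd.DataFrame({
            "chrom": 1, "pos": np.arange(1, m + 1) * 1000, "id": ids,
            "a1": "A", "a2": "G", "freq": 0.4, "n": 100,
            "beta": betas, "se": ses, "p": 0.5, "test": "additive"})

    def test_single_stratum_identity(self):
        rec = self._records([0.1, -0.2], [0.02, 0.03])
        meta = vg.meta_ivw([rec])
        assert np.allclose(meta["beta"], rec["beta"])
        assert (meta["test"] == "meta").all()

    def test_equal_se_gives_mean(self):
        r1 = self._records([0.1], [0.02])
        r2 = self._records([0.3], [0.02])
        meta = vg.meta_ivw([r1, r2])
        assert meta["beta"].iloc[0] == pytest.approx(0.2)
        assert meta["se"].iloc[0] == pytest.approx(0.02 / np.sqrt(2))

    def test_hand_arithmetic(self):
        # w = (2500, 10000); beta = (250 + 200)/12500 = 0.036
        r1 = self._records([0.10], [0.02])
        r2 = self._records([0.02], [0.01])
        meta = vg.meta_ivw([r1, r2])
        assert meta["beta"].iloc[0] == pytest.approx(0.036)
        assert meta["se"].iloc[0] == pytest.approx(1 / np.sqrt(12500))

    def test_allele_flip_harmonized(self):
        r1 = self._records([0.1], [0.02])
        r2 = self._records([-0.1], [0.02])
        r2[["a1", "a2"]] = r2[["a2", "a1"]].to_numpy()
        r2["freq"] = 0.6
        meta = vg.meta_ivw([r1, r2])
        assert meta["beta"].iloc[0] == pytest.approx(0.1)
        assert meta["n"].iloc[0] == 200


class TestPolygenicScore:
    def test_zero_weights_zero_scores(self):
        geno = _sim(n=50, m=10, seed=61)
        w = pd.DataFrame({"id": geno.variants["id"], "effect_allele": "A",
                          "weight": 0.0})
        assert np.allclose(vg.polygenic_score(geno, w), 0.0)

    def test_single_unit_weight_returns_dosage(self):
        geno = _sim(n=50, m=10, seed=62)
        w = pd.DataFrame({"id": ["snp000003"], "effect_allele": ["A"],
                          "weight": [1.0]})
        assert np.allclose(vg.polygenic_score(geno, w),
                           geno.values[:, 3].astype(float))

    def test_true_weights_track_genetic_value(self):
        geno = _sim(n=5000, m=100, seed=63)
        rng = np.random.default_rng(9163)
        betas = rng.standard_normal(100) * 0.05
        gv = geno.values.astype(float) @ betas
        w = pd.DataFrame({"id": geno.variants["id"], "effect_allele": "A",
                          "weight": betas})
        score = vg.polygenic_score(geno, w)
        assert np.corrcoef(score, gv)[0, 1] > 0.95

    def test_no_overlap_rejected(self):
        geno = _sim(n=20, m=10, seed=64)
        w = pd.DataFrame({"id": ["nope"], "effect_allele": ["A"],
                          "weight": [1.0]})
        with pytest.raises(ValueError):
            vg.polygenic_score(geno, w)
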