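import numpy as np
import pytest
from scipy import stats

from zieqtl import lmm
from zieqtl.datatypes import GenotypeMatrix, ValidationError


def toy_genotypes(dosage, pos=None):
    dosage = np.asarray(dosage, dtype=float)
    m = dosage.shape[1]
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    return GenotypeMatrix(
        [f"a{i}" for i in range(dosage.shape[0])],
        [f"chr1_{p}" for p in pos],
        ["chr1"] * m,
        pos,
        dosage,
    )


def grm_double_loop(dosage):
    """Naive O(n^2 M) oracle for the frequency-weighted GRM."""
    d = dosage.copy()
    mu = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = mu[inds[1]]
    p = mu / 2
    n, m = d.shape
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for s in range(m):
                acc += (d[i, s] - 2 * p[s]) * (d[j, s] - 2 * p[s]) / (
                    2 * p[s] * (1 - p[s])
                )
            k[i, j] = acc / m
    return k


class TestGrm:
    def test_row_sums_zero_pre_regularization(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], (15, 40))
        g = toy_genotypes(d)
        K = lmm.grm_freq(g, regularization=0.0)
        np.testing.assert_allclose(K.k.sum(axis=1), 0.0, atol=1e-10)

    def test_duplicated_accession_offdiag_equals_diag(self, rng):
        d = rng.choice([0.0, 2.0], (10, 30))
        d[1] = d[0]
        K = lmm.grm_freq(toy_genotypes(d), regularization=0.0)
        assert K.k[0, 1] == pytest.approx(K.k[0, 0], rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        d = rng.choice([0.0, 1.0, 2.0], (20, 25)).astype(float)
        d[rng.random((20, 25)) < 0.05] = np.nan
        K = lmm.grm_freq(toy_genotypes(d), regularization=0.0)
        np.testing.assert_allclose(K.k, grm_double_loop(d), atol=1e-12)

    def test_monomorphic_snp_rejected(self):
        d = np.column_stack([np.full(8, 2.0), [0, 0, 0, 0, 2, 2, 2, 2.0]])
        with pytest.raises(ValidationError):
            lmm.grm_freq(toy_genotypes(d))


class TestRankInverseNormal:
    def test_two_values_give_quartile_quantiles(self):
        out = lmm.rank_inverse_normal(np.array([5.0, 7.0]))
        np.testing.assert_allclose(
            out, [stats.norm.ppf(0.25), stats.norm.ppf(0.75)], atol=1e-4
        )
        assert out[0] == pytest.approx(-0.6745, abs=1e-4)

    def test_mean_zero_for_tie_free_input(self, rng):
        out = lmm.rank_inverse_normal(rng.random(31))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.random(25)
        np.testing.assert_allclose(
            lmm.rank_inverse_normal(y), lmm.rank_inverse_normal(np.exp(3 * y))
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            lmm.rank_inverse_normal(np.ones(10))


class TestPolygenicFit:
    def test_identity_kinship_flags_flat_objective(self, rng):
        K = lmm.KinshipMatrix([f"a{i}" for i in range(30)], np.eye(30))
        fit = lmm.fit_polygenic(rng.standard_normal(30), K)
        assert fit.flat_objective
        assert fit.h2 == 0.0

    def test_pure_noise_gives_low_h2(self, rng):
        n = 150
        d = rng.choice([0.0, 2.0], (n, 300), p=[0.6, 0.4])
        K = lmm.grm_freq(toy_genotypes(d))
        fit = lmm.fit_polygenic(rng.standard_normal(n), K)
        assert fit.h2 < 0.35

    def test_recovers_moderate_heritability(self, rng):
        # block-relatedness structure: 30 families of 5
        n = 150
        K = np.kron(np.eye(30), np.full((5, 5), 0.6)) + 0.4 * np.eye(n)
        L = np.linalg.cholesky(K)
        y = np.sqrt(0.6) * (L @ rng.standard_normal(n)) + np.sqrt(0.4) * (
            rng.standard_normal(n)
        )
        fit = lmm.fit_polygenic(y, lmm.KinshipMatrix([f"a{i}" for i in range(n)], K))
        assert 0.3 < fit.h2 < 0.9


class TestMmscore:
    def test_reduces_to_ols_score_test_when_h2_zero(self, rng):
        n = 50
        d = rng.choice([0.0, 1.0, 2.0], (n, 10))
        g = toy_genotypes(d)
        y = rng.standard_normal(n)
        K = lmm.KinshipMatrix(g.accession_ids, np.eye(n))
        fit = lmm.fit_polygenic(y, K)
        res = lmm.mmscore_scan(fit, g)
        yc = y - y.mean()
        s2 = (yc @ yc) / (n - 1)
        for j in range(10):
            gc = d[:, j] - d[:, j].mean()
            expected = (gc @ yc) ** 2 / (gc @ gc) / s2
            # sigma2 is the REML residual variance, same ddof as the OLS form
            assert res.stat[j] == pytest.approx(expected, rel=1e-8)

    def test_matches_explicit_gls_oracle(self, rng):
        n = 30
        d = rng.choice([0.0, 2.0], (n, 8), p=[0.5, 0.5])
        g = toy_genotypes(d)
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        Km = lmm.KinshipMatrix(g.accession_ids, K)
        y = rng.standard_normal(n)
        fit = lmm.fit_polygenic(y, Km)
        res = lmm.mmscore_scan(fit, g)
        V = fit.sigma_g2 * K + fit.sigma_e2 * np.eye(n)
        Vinv = np.linalg.inv(V)
        yt = y - fit.beta0
        for j in range(8):
            gc = d[:, j] - d[:, j].mean()
            T = (gc @ Vinv @ yt) ** 2 / (gc @ Vinv @ gc)
            assert res.stat[j] == pytest.approx(T, rel=1e-8, abs=1e-10)

    def test_planted_additive_effect_detected(self, default_dataset):
        from zieqtl.io import filter_genotypes

        ds = default_dataset
        g = filter_genotypes(ds.genotypes)
        K = lmm.grm_freq(g)
        eig = np.linalg.eigh(K.k)
        hits, tested = 0, 0
        for rec in ds.truth.by_type("additive"):
            v = ds.expression.gene_vector(rec["gene_id"])
            if np.unique(v).size < 3:
                continue
            y = lmm.rank_inverse_normal(v)
            fit = lmm.fit_polygenic(y, K, eig=eig)
            res = lmm.mmscore_scan(fit, g, gene_id=rec["gene_id"])
            tested += 1
            if res.min_p < 1e-4:
                hits += 1
        assert tested >= 5
        assert hits / tested > 0.5


class TestGenomeWideThreshold:
    def _setup(self, rng, n=80, m=300, n_traits=12):
        d = rng.choice([0.0, 2.0], (n, m), p=[0.6, 0.4])
        g = toy_genotypes(d)
        K = lmm.grm_freq(g)
        eig = np.linalg.eigh(K.k)
        fits, scans = {}, {}
        for t in range(n_traits):
            j = rng.integers(m)
            y = d[:, j] / 2 * 1.5 + rng.standard_normal(n)
            fit = lmm.fit_polygenic(y, K, eig=eig)
            fits[f"t{t}"] = fit
            scans[f"t{t}"] = lmm.mmscore_scan(fit, g, gene_id=f"t{t}")
        return g, fits, scans

    def test_pool_size_and_quantile_definition(self, rng):
        g, fits, scans = self._setup(rng)
        rep = lmm.genome_wide_threshold(
            fits, scans, g, prescreen_p=1e-3, n_traits_sample=5, n_perm=40,
            level=0.01, seed=9,
        )
        assert rep.n_perm_total == 5 * 40
        assert rep.threshold_p > 0

    def test_threshold_monotone_in_level(self, rng):
        g, fits, scans = self._setup(rng)
        kw = dict(prescreen_p=1e-3, n_traits_sample=5, n_perm=40, seed=9)
        t1 = lmm.genome_wide_threshold(fits, scans, g, level=0.01, **kw)
        t5 = lmm.genome_wide_threshold(fits, scans, g, level=0.05, **kw)
        assert t5.threshold_p >= t1.threshold_p

    def test_no_prescreen_survivor_errors(self, rng):
        g, fits, scans = self._setup(rng)
        with pytest.raises(ValueError, match="prescreen"):
            lmm.genome_wide_threshold(fits, scans, g, prescreen_p=1e-300)

    def test_null_calibration(self, rng):
        """Independent null traits exceed the 1% threshold about 1% of the time."""
        n, m = 100, 400
        d = rng.choice([0.0, 2.0], (n, m), p=[0.6, 0.4])
        g = toy_genotypes(d)
        K = lmm.grm_freq(g)
        eig = np.linalg.eigh(K.k)
        # threshold from a handful of strong traits
        fits, scans = {}, {}
        for t in range(6):
            j = rng.integers(m)
            y = d[:, j] * 2 + rng.standard_normal(n)
            fit = lmm.fit_polygenic(y, K, eig=eig)
            fits[f"t{t}"] = fit
            scans[f"t{t}"] = lmm.mmscore_scan(fit, g, gene_id=f"t{t}")
        rep = lmm.genome_wide_threshold(
            fits, scans, g, prescreen_p=1e-4, n_traits_sample=6, n_perm=150,
            level=0.01, seed=4,
        )
        rejections = 0
        n_null = 300
        for t in range(n_null):
            y = rng.standard_normal(n)
            fit = lmm.fit_polygenic(y, K, eig=eig)
            res = lmm.mmscore_scan(fit, g)
            rejections += res.min_p < rep.threshold_p
        rate = rejections / n_null
        # binomial 99% envelope around 0.01 with n = 300
        assert rate < 0.01 + 2.6 * np.sqrt(0.01 * 0.99 / n_null) + 1e-9
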