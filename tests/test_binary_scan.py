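import numpy as np
import pytest
from scipy import stats

from zieqtl import binary_scan as bs
from zieqtl.datatypes import GenotypeMatrix
from zieqtl.selection import binarize


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


class TestLogisticScoreTest:
    def test_hand_computed_example(self):
        stat, p = bs.logistic_score_test([1, 1, 0, 0], [2, 2, 0, 0])
        assert stat == pytest.approx(4.0)
        assert p == pytest.approx(0.04550026, abs=1e-6)

    def test_symmetric_null_gives_zero_statistic(self):
        stat, p = bs.logistic_score_test([1, 0, 1, 0], [2, 2, 0, 0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_invariant_under_affine_rescaling_of_dosage(self, rng):
        y = rng.integers(0, 2, 30).astype(float)
        y[:3] = 1
        y[-3:] = 0
        g = rng.choice([0.0, 1.0, 2.0], 30)
        s1, _ = bs.logistic_score_test(y, g)
        s2, _ = bs.logistic_score_test(y, 5.0 * g - 3.0)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_constant_inputs_return_nan_not_exception(self):
        assert np.isnan(bs.logistic_score_test([1, 1, 1], [0, 1, 2])[0])
        assert np.isnan(bs.logistic_score_test([1, 0, 1], [2, 2, 2])[0])

    def test_missing_entries_dropped_pairwise(self):
        stat, _ = bs.logistic_score_test(
            [1, 1, 0, 0, 1], [2, 2, 0, 0, np.nan]
        )
        ref, _ = bs.logistic_score_test([1, 1, 0, 0], [2, 2, 0, 0])
        assert stat == pytest.approx(ref)

    def test_agrees_with_full_likelihood_lrt_decisions(self, rng):
        """Score test decisions match an iterative ML logistic fit at alpha=.05
        away from the significance boundary (n = 12 random tables)."""
        from statsmodels.api import Logit, add_constant

        checked = 0
        for _ in range(300):
            y = rng.integers(0, 2, 12).astype(float)
            g = rng.choice([0.0, 1.0, 2.0], 12)
            stat, p_score = bs.logistic_score_test(y, g)
            if not np.isfinite(stat):
                continue
            try:
                fit = Logit(y, add_constant(g)).fit(disp=0, maxiter=200)
                p_lrt = stats.chi2.sf(fit.llr, 1)
            except Exception:
                continue  # separation: ML fit has no finite optimum
            if not np.isfinite(p_lrt):
                continue
            if not fit.mle_retvals.get("converged", True) or np.abs(fit.params).max() > 8:
                continue  # (quasi-)separated table, no finite ML optimum
            if min(abs(p_lrt - 0.05), abs(p_score - 0.05)) < 0.02:
                continue  # boundary cases excluded from the decision check
            assert (p_score < 0.05) == (p_lrt < 0.05)
            checked += 1
        assert checked > 50

    def test_vectorized_scan_matches_scalar_path(self, rng):
        y = rng.integers(0, 2, 40).astype(float)
        y[0], y[1] = 1, 0
        G = rng.choice([0.0, 1.0, 2.0], (40, 15))
        stat_v, p_v, _ = bs.score_test_scan(y, G)
        for j in range(15):
            s, p = bs.logistic_score_test(y, G[:, j])
            if np.isnan(s):
                assert np.isnan(stat_v[j])
            else:
                assert stat_v[j] == pytest.approx(s, rel=1e-12)


class TestFirth:
    def test_balanced_null_gives_zero_log_or(self):
        log_or, se = bs.firth_logor([1, 0, 1, 0], [1, 1, 0, 0])
        assert log_or == pytest.approx(0.0, abs=1e-8)
        assert se > 0

    def test_finite_under_complete_separation(self):
        g = np.array([0, 0, 0, 0, 0, 2, 2, 2, 2, 2.0])
        y = g / 2
        log_or, se = bs.firth_logor(y, g)
        assert np.isfinite(log_or) and np.isfinite(se)
        assert log_or > 0

    def test_recovers_planted_effect_within_two_se(self, rng):
        n = 500
        g = rng.choice([0.0, 2.0], n, p=[0.7, 0.3])
        eta = -1.5 + 2.0 * g / 2  # slope 1.0 per dosage unit
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        log_or, se = bs.firth_logor(y, g)
        assert abs(log_or - 1.0) < 2 * se


class TestScanAndPermutation:
    def test_single_snp_window_min_p_is_that_snp(self):
        g = toy_genotypes([[2], [2], [0], [0]])
        w = bs.CisWindow("g", "chr1", 1, 10_000, np.array([0]))
        res = bs.scan_gene(np.array([1, 1, 0, 0.0]), w, g)
        assert res.min_p == pytest.approx(res.p_value[0])
        assert res.top_snp == g.snp_ids[0]

    def test_tie_break_prefers_smallest_position(self):
        d = np.array([[2, 2], [2, 2], [0, 0], [0, 0.0]])
        g = toy_genotypes(d, pos=[500, 900])
        w = bs.CisWindow("g", "chr1", 1, 10_000, np.array([0, 1]))
        res = bs.scan_gene(np.array([1, 1, 0, 0.0]), w, g)
        assert res.top_snp == "chr1_500"

    def test_permutation_threshold_is_kth_smallest(self, rng):
        d = rng.choice([0.0, 2.0], (40, 30))
        g = toy_genotypes(d)
        y = rng.integers(0, 2, 40).astype(float)
        y[0], y[1] = 1, 0
        w = bs.CisWindow("g", "chr1", 1, 100_000, np.arange(30))
        null = bs.permutation_null(y, w, g, n_perm=500, level=0.01, seed=3)
        assert null.threshold == pytest.approx(np.sort(null.minp_null)[4])

    def test_empirical_p_floor_when_observed_beats_all_nulls(self):
        # deterministic genotype-phenotype coupling -> observed min-P tiny
        n = 60
        d = np.zeros((n, 20))
        d[: n // 2, 0] = 2
        rng = np.random.default_rng(0)
        d[:, 1:] = rng.choice([0.0, 2.0], (n, 19))
        g = toy_genotypes(d)
        y = (d[:, 0] / 2).astype(float)
        w = bs.CisWindow("g", "chr1", 1, 100_000, np.arange(20))
        null = bs.permutation_null(y, w, g, n_perm=1000, level=0.01, seed=1)
        assert null.empirical_p == pytest.approx(1 / 1001)

    def test_planted_presence_gene_top_snp_in_ld_with_causal(self, default_dataset):
        ds = default_dataset
        planted = ds.truth.by_type("presence")
        b = binarize(ds.expression)
        hits = 0
        tested = 0
        for rec in planted:
            y = b.gene_vector(rec["gene_id"]).astype(float)
            if y.sum() in (0, len(y)):
                continue
            w = bs.CisWindow.around_tss(rec["gene_id"], ds.annotation, ds.genotypes)
            res = bs.scan_gene(y, w, ds.genotypes, fit_effect=False)
            if res.top_index is None:
                continue
            tested += 1
            causal = ds.genotypes.snp_index(rec["causal_snp_id"])
            dist = abs(ds.genotypes.pos[causal] - ds.genotypes.pos[res.top_index])
            if dist <= 100_000:  # within the simulated LD block span
                hits += 1
        assert tested >= 5
        assert hits / tested > 0.5

    def test_discover_is_deterministic_under_seed(self, small_dataset):
        from zieqtl.selection import select_variable_genes

        ds = small_dataset
        b = binarize(ds.expression)
        sel = select_variable_genes(ds.expression, b)
        d1 = bs.discover(b, ds.genotypes, ds.annotation, sel.selected_gene_ids,
                         n_perm=200, seed=42)
        d2 = bs.discover(b, ds.genotypes, ds.annotation, sel.selected_gene_ids,
                         n_perm=200, seed=42)
        assert d1.significant_genes == d2.significant_genes
        for gid in d1.nulls:
            assert d1.nulls[gid].threshold == d2.nulls[gid].threshold
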