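import numpy as np
import pytest

from zieqtl.sim import (
    ConfigError,
    SimConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_replication_dataset,
    load_dataset,
    write_dataset,
)


def hudson_fst(dosage, subpop):
    """Independent ratio-of-averages Hudson-style Fst estimator.

    Inbred diploids are treated as haploid samples (dosage / 2).
    """
    h = dosage / 2.0
    p1 = h[subpop == 0].mean(axis=0)
    p2 = h[subpop == 1].mean(axis=0)
    n1 = (subpop == 0).sum()
    n2 = (subpop == 1).sum()
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return num[keep].sum() / den[keep].sum()


class TestGenotypeSimulation:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_accessions=30, snps_per_chrom=200, n_genes=10, seed=5)
        g1 = simulate_genotypes(cfg)
        g2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)
        assert g1.snp_ids == g2.snp_ids

    def test_inbred_dosages_are_homozygous(self):
        g = simulate_genotypes(SimConfig(n_accessions=20, snps_per_chrom=100, seed=1))
        assert set(np.unique(g.dosage)) <= {0.0, 2.0}

    def test_low_fst_limit_matches_ancestral_frequencies(self):
        # Beta variance -> 0, so subpopulation frequencies coincide
        cfg = SimConfig(
            n_accessions=400, n_subpops=2, fst=1e-4, n_chrom=1,
            snps_per_chrom=300, seed=9, ld_leak=1.0,
        )
        g = simulate_genotypes(cfg)
        sub = np.arange(400) % 2
        p1 = g.dosage[sub == 0].mean(axis=0) / 2
        p2 = g.dosage[sub == 1].mean(axis=0) / 2
        assert np.mean(np.abs(p1 - p2)) < 0.06  # binomial sampling noise only

    def test_fst_recovery(self):
        cfg = SimConfig(
            n_accessions=200, n_subpops=2, fst=0.3, n_chrom=1,
            snps_per_chrom=2000, seed=11,
        )
        g = simulate_genotypes(cfg)
        sub = np.arange(200) % 2
        est = hudson_fst(g.dosage, sub)
        assert est == pytest.approx(0.3, abs=0.05)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(fst=0.0)


class TestExpressionSimulation:
    def test_sv_carriers_have_zero_expression_and_mask(self):
        cfg = SimConfig(
            n_accessions=80, snps_per_chrom=500, n_genes=30, seed=3,
            frac_sv_genes=0.2, dropout_tau=0.0,
        )
        ds = simulate_dataset(cfg)
        masks = {m.accession_id: m for m in ds.masks}
        sv_genes = ds.truth.by_type("sv_deletion")
        assert sv_genes, "expected planted deletion genes"
        for rec in sv_genes:
            vec = ds.expression.gene_vector(rec["gene_id"])
            info = ds.annotation.gene(rec["gene_id"])
            for acc in rec["carrier_accessions"]:
                i = ds.expression.accession_ids.index(acc)
                assert vec[i] == 0.0
                m = masks[acc]
                if rec["sv_type"] == "gene_body_gap":
                    assert m.contains_interval(
                        info.chrom, int(info.start), int(info.end)
                    )
                else:
                    assert m.covers_point(info.chrom, int(info.tss))

    def test_no_dropout_no_effects_gives_no_zeros(self):
        cfg = SimConfig(
            n_accessions=50, snps_per_chrom=300, n_genes=20, seed=4,
            frac_presence_genes=0, frac_sv_genes=0, frac_additive_genes=0,
            dropout_tau=0.0,
        )
        ds = simulate_dataset(cfg)
        assert (ds.expression.values > 0).all()

    def test_dropout_rate_decreases_with_expression(self):
        cfg = SimConfig(
            n_accessions=100, snps_per_chrom=300, n_genes=40, seed=6,
            frac_presence_genes=0, frac_sv_genes=0, frac_additive_genes=0,
            dropout_tau=2.0,
        )
        ds = simulate_dataset(cfg)
        v = ds.expression.values
        det = (v > 0).mean(axis=0)
        means = np.where((v > 0).any(axis=0), v.sum(0) / np.maximum((v > 0).sum(0), 1), 0)
        lo = det[means < np.median(means)].mean()
        hi = det[means >= np.median(means)].mean()
        assert hi > lo

    def test_presence_effect_recovered_by_logistic_refit(self):
        from statsmodels.api import Logit, add_constant

        cfg = SimConfig(
            n_accessions=140, snps_per_chrom=800, n_genes=30, seed=8,
            frac_presence_genes=0.3, frac_sv_genes=0, frac_additive_genes=0,
            dropout_tau=0.0, effect_size_logor=3.0,
        )
        ds = simulate_dataset(cfg)
        recovered = 0
        tested = 0
        for rec in ds.truth.by_type("presence"):
            y = (ds.expression.gene_vector(rec["gene_id"]) > 0).astype(float)
            gdx = ds.genotypes.dosage[:, ds.genotypes.snp_index(rec["causal_snp_id"])]
            if y.min() == y.max():
                continue
            try:
                fit = Logit(y, add_constant(gdx)).fit(disp=0)
            except Exception:
                continue
            tested += 1
            b = fit.params[1] * 2  # slope per dosage unit * dosage range
            if abs(b - 3.0) < 2 * fit.bse[1] * 2:
                recovered += 1
        assert tested >= 3
        assert recovered / tested > 0.5


class TestDatasetRoundTrip:
    def test_write_load_identity(self, tmp_path, small_dataset):
        write_dataset(tmp_path / "d", small_dataset)
        back = load_dataset(tmp_path / "d")
        np.testing.assert_array_equal(
            back.expression.values, small_dataset.expression.values
        )
        # loader may re-orient dosage to the minor allele; MAF must agree
        np.testing.assert_allclose(
            back.genotypes.compute_maf(), small_dataset.genotypes.compute_maf(),
            atol=1e-12,
        )
        assert back.annotation.df.equals(small_dataset.annotation.df)
        assert back.truth.records == small_dataset.truth.records

    def test_refuses_nonempty_outdir(self, tmp_path, small_dataset):
        out = tmp_path / "d"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_dataset(out, small_dataset)

    def test_truth_counts_match_config(self, small_dataset):
        # 20 genes at the fixture fractions: 4 presence, 2 sv, 4 additive
        assert len(small_dataset.truth.by_type("presence")) <= 4
        assert len(small_dataset.truth.by_type("sv_deletion")) <= 2
        n_masks = len(small_dataset.masks)
        assert n_masks == 60
        carriers = {
            a for r in small_dataset.truth.by_type("sv_deletion")
            for a in r["carrier_accessions"]
        }
        for m in small_dataset.masks:
            has_iv = any(len(v) for v in m.intervals.values())
            assert has_iv == (m.accession_id in carriers)


class TestReplicationPanel:
    def test_shares_snp_map_and_truth(self, small_dataset):
        cfg = SimConfig(
            n_accessions=60, snps_per_chrom=400, n_genes=20, seed=7, dropout_tau=0.3
        )
        ds2 = simulate_replication_dataset(cfg, small_dataset.truth, seed=99)
        assert ds2.genotypes.snp_ids == small_dataset.genotypes.snp_ids
        assert ds2.genotypes.accession_ids != small_dataset.genotypes.accession_ids
        t1 = {r["gene_id"]: r["effect_type"] for r in small_dataset.truth.records}
        t2 = {r["gene_id"]: r["effect_type"] for r in ds2.truth.records}
        shared = {g for g in t1 if t1[g] != "none" and t2[g] != "none"}
        assert shared  # planted effects carry over to the second panel
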