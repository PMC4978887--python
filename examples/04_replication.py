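"""Replicate discovery cis-eQTL in an independent second panel.

The replication panel shares the SNP map and planted gene effects but has
fresh accessions and noise. Each discovery peak is retested on all SNPs
within +/- 10 kb; replication requires beating alpha / n_region_snps and
sign-consistent effects on the SNPs shared between the panels.
"""

from zieqtl import binary_scan as bs, peaks as pks, replication as rep
from zieqtl.selection import binarize, select_variable_genes
from zieqtl.sim import SimConfig, simulate_dataset, simulate_replication_dataset

cfg = SimConfig(n_accessions=100, snps_per_chrom=800, n_genes=40, seed=11)
ds = simulate_dataset(cfg)
ds2 = simulate_replication_dataset(cfg, ds.truth, seed=77)

b = binarize(ds.expression)
sel = select_variable_genes(ds.expression, b)
disc = bs.discover(b, ds.genotypes, ds.annotation, sel.selected_gene_ids,
                   seed=3, n_perm=300)
b2 = binarize(ds2.expression)

n_rep = tested = 0
for gid in disc.significant_genes:
    res = disc.results[gid]
    pk = pks.EqtlPeak(gid, res.top_snp, str(ds.genotypes.chrom[res.top_index]),
                      int(ds.genotypes.pos[res.top_index]), res.min_p)
    y2 = b2.gene_vector(gid).astype(float)
    pheno = y2 if 0 < y2.sum() < len(y2) else None
    rr = rep.replicate(pk, pheno, ds2.genotypes, "binary",
                       discovery_result=res, genotypes1=ds.genotypes,
                       alpha=0.05, sign_rule="majority")
    if rr.reason != "not_expressed":
        tested += 1
        n_rep += rr.replicated
    print(f"  {gid}: best regional P {rr.best_p:.2e} vs {rr.region_threshold:.1e}, "
          f"signs {rr.sign_consistent} -> replicated={rr.replicated}")

fdr = rep.replication_fdr(tested, n_rep, 0.05) if n_rep else None
print(f"replicated {n_rep} of {tested} testable discovery eQTL"
      + (f" (FDR = {fdr.q:.3f})" if fdr else ""))
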