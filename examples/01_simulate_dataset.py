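"""Simulate a panel of inbred accessions with known planted effects.

The generator emulates a worldwide collection of naturally inbred lines:
Balding-Nichols population structure, LD blocks, log-normal expression with
a polygenic component, planted presence/absence and additive cis effects,
deletion alleles that zero expression and punch coverage gaps, and
level-dependent detection dropout.
"""

from collections import Counter

from zieqtl.sim import SimConfig, simulate_dataset

cfg = SimConfig(seed=1)  # defaults: 140 accessions, 2 x 2000 SNPs, 60 genes
ds = simulate_dataset(cfg)

print(f"genotypes: {ds.genotypes.n_accessions} accessions x {ds.genotypes.n_snps} SNPs")
print(f"expression: {len(ds.expression.gene_ids)} genes")
types = Counter(r["effect_type"] for r in ds.truth.records)
print("planted effects:", dict(types))
zeros = (ds.expression.values == 0).mean()
print(f"zero fraction of the expression matrix: {zeros:.2f}")
# The zero entries mix three causes: planted presence/absence alleles,
# deletion carriers, and detection dropout for low-expressed genes.
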