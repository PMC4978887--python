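# Methods

## Setting

The package targets panels of naturally inbred accessions genotyped
genome-wide and phenotyped by RNA-seq. Two features dominate the analysis
design: (i) transcript abundance for many genes is zero-inflated —
abundant in some accessions, absent in others — and (ii) the panel is
structured (related accessions share ancestry), so quantitative
association must correct for kinship. Coordinates are 1-based inclusive
throughout; BED input is converted at the IO boundary. Dosages count the
minor allele; inbred accessions carry dosages in {0, 2}.

## Quality control

SNPs are kept when minor-allele frequency is **strictly above** 0.05
("above" read as strict) and call rate is at least 0.95. Missing dosages
are mean-imputed only inside kinship construction; everywhere else they
are dropped pairwise, which keeps the small-sample tests exact.
Accessions with anomalously few detected transcripts can be dropped
either by explicit list or by a robust rule (detected-gene count below
median − 4·MAD); the robust rule is this package's construction — the
motivating analyses name removed accessions without stating a rule — and
MAD = 0 degenerates to dropping nothing.

## Gene selection and binarization

A transcript is *present* when its normalized abundance is strictly
positive (an abundance can never be negative, so "absent" is exactly
zero). Genes enter the presence/absence scan when (i) their presence
count lies strictly between 10% and 90% of the panel and (ii) their mean
abundance over the accessions where they are detected exceeds that of the
2nd-lowest-expressed gene among genes detected in every accession. The
floor removes most genes whose zeros are plausibly detection dropout:
detection probability falls with expression level, so genes expressed
above the always-detected floor but still missing in many accessions are
the candidates for genetic presence/absence control. Whether the floor
should use mean, median or maximum expression is genuinely open; the mean
is used because the detection-trend summaries are also built on means.

## Presence/absence cis scan

Each selected gene is scanned over SNPs within ±1 Mb of its TSS with the
intercept-only logistic **score test**: U = Σ gᵢ(yᵢ − ȳ),
V = ȳ(1−ȳ)·Σ(gᵢ−ḡ)², U²/V against χ²(1). The score test (rather than
Wald/LRT) is used because presence can separate perfectly on genotype, in
which case the ML estimate diverges while the score statistic stays
defined. For the same reason the reportable effect at the top SNP is a
**Firth** penalized-likelihood log odds ratio (Jeffreys prior, Newton
iterations with step-halving), which is finite under complete separation.
Kinship is deliberately not used in this scan; it is a plain logistic
association.

Significance combines two filters:

1. window Bonferroni at base α = 0.05 over the window's SNP count;
2. a trait-specific threshold: the binarized phenotype is shuffled 1000
   times against the cis genotypes, each shuffle rescanned, and the
   threshold taken as the floor(0.01·1000)-th smallest null min-P (the
   1% cut). The empirical P carries the +1 correction so it is never 0.
   Comparisons are strict (<). With inbred (0/2) dosages the score
   statistic is discrete, so observed/null min-P ties are possible and
   the strict comparison makes the test mildly conservative on tie-prone
   panels; calibration checks should use the binomial interval of the
   trait count, not a point match.

The FDR over traits is the empirical **Q = E(V/R) = α·T/R** (α the
permutation level, T traits scanned, R traits significant); R = 0 reports
NA rather than a division.

## Kinship and the quantitative scan

The genomic relationship matrix is frequency-weighted (VanRaden-type):
k_ij = (1/M) Σ_m (g_im − 2p_m)(g_jm − 2p_m) / (2p_m(1−p_m)) with sample
allele frequencies; rows sum to exactly zero by construction, and 1e-8 is
added to the diagonal for PSD stability. Expression is transformed by the
rank-based inverse-normal map Φ⁻¹((rank−0.5)/n) (average ranks on ties) —
the standard realization of "inverse-Gaussian transformed" phenotypes in
the GenABEL lineage.

The polygenic model y = Xβ + u + e, u ~ N(0, σ²_g K), e ~ N(0, σ²_e I) is
fitted by REML reduced to one dimension on the eigenbasis of K: one
eigendecomposition (reused across genes), a 25-point grid over
h² = σ²_g/(σ²_g+σ²_e) and bounded refinement. A flat objective (e.g.
K = I, where h² is unidentifiable) returns h² = 0 with a flag. Per-SNP
association is the **mmscore** statistic (g̃ᵀV⁻¹ỹ)²/(g̃ᵀV⁻¹g̃), which
reduces to the ordinary linear score test at h² = 0.

The genome-wide threshold follows the GRAMMAR+ trick: traits with any
SNP at P < 1e-6 are eligible; up to 200 are sampled; each contributes 200
permutations of its standardized residuals r = V⁻¹(y − Xβ̂) rescanned
with the naive score test (no REML refit — the point of the trick, and
the only way 40,000 scans are tractable); the pooled min-P distribution's
1% quantile is the threshold. Both the mmscore statistic on the observed
phenotype and the naive statistic on permuted residuals are χ²(1)-
calibrated, so the pooled null is comparable to the observed scan; the
null-calibration test verifies this empirically.

## Peaks, classification, replication

Significant SNPs of a gene are merged single-linkage with gap ≤ 1 Mb
(inclusive); the lead SNP is the min-P SNP, ties broken toward the
smaller position for determinism. A peak is **cis** when the lead SNP
lies on the gene's chromosome within 1 Mb (inclusive) of the nearest
gene-body endpoint — anchoring at the gene body rather than the TSS is a
documented choice; the signed TSS distance is reported alongside for
summaries.

Replication rescans all second-panel SNPs within ±10 kb of a discovery
peak (10 kb ≈ the expected LD-block scale of the motivating system) with
the matching test, at a Bonferroni threshold α/n_region_snps, and
requires sign-consistent effects on SNPs shared between panels at
identical (chromosome, position). The default demands *all* shared SNPs
agree (strict reading); a majority rule is available behind
`sign_rule="majority"` and is the practical choice when the region holds
several noise SNPs. Zero shared SNPs is "untestable" and counts as not
replicated. Replication FDR is again α·T/R; the α used in the motivating
analyses is internally inconsistent (0.05 stated, 0.01 implied by one
printed rate), so α is always an explicit parameter.

## Covariance correlation and structural variants

The binary relationship matrix applies the GRM formula to presence calls:
r_ij = (1/G) Σ_g (b_ig − p_g)(b_jg − p_g)/(p_g(1−p_g)), requiring
presence frequencies strictly inside (0,1). Its Pearson correlation with
the kinship is computed over strictly-upper-triangle elements (diagonals
are inbreeding-like terms, not pairwise sharing — their exclusion is a
documented choice). The parametric P treats n(n−1)/2 pairs as independent
and is reported for comparability only; the Mantel permutation P is the
defensible test. n_genes·r, truncated to an integer, is the expected
excess of shared transcripts between genetically identical accessions
relative to unrelated ones.

A gene carries a **TSS gap** in an accession when the TSS base falls in a
zero-coverage interval (a `--tss-window` widens this; default 0 because
no extent is canonically defined) and a **gene-body gap** when
[start, end] is contained in one merged zero-coverage run (abutting
intervals merge, so splitting a mask interval cannot change calls). Gaps
shared by strictly more than 5 accessions become SV calls, tested against
transcript presence with a two-sided Fisher exact test; the Bonferroni
denominator is the number of SV genes in the analysis batch. The odds
ratio is the sample OR with 0.5 continuity correction.

## Synthetic data

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_accessions | 140 | panel size after QC in the motivating analyses |
| n_subpops / fst | 3 / 0.2 | Balding–Nichols structure of a worldwide collection |
| n_chrom × snps_per_chrom | 2 × 2000 | desk-scale marker map (12 Mb chromosomes) |
| ld_block_span / ld_leak | 100 kb / 0.1 | LD blocks; span scaled up ~10× because marker density is ~50× sparser than real panels, keeping ~20 SNPs per block |
| n_genes | 60 | desk-scale transcriptome |
| frac presence/additive/sv | 0.2 / 0.2 / 0.1 | planted effect mix |
| effect_size_logor | 3 | presence log-odds across the dosage range (1.5 per dosage unit) |
| effect_size_beta | 1 | additive effect in residual-SD units |
| h2_polygenic | 0.3 | kinship-structured share of log-expression variance |
| baseline_log_mean/sd | 2 / 1.5 | log-normal abundance baseline |
| dropout_tau | 0.5 | detection dropout P(drop) = exp(−abundance/τ) |

Genotypes follow the Balding–Nichols model (ancestral frequency
U(0.05, 0.95); subpopulation frequencies Beta-distributed at the given
Fst); accessions are inbred (one allele doubled; a switch permits
heterozygotes). LD uses a comonotone coupling: one uniform per
(accession, block) with a per-SNP leak to a fresh uniform — marginals
stay exactly Balding–Nichols, so Fst recovery is unbiased, while SNPs in
a block are strongly correlated. Genes are placed uniformly with ≥ 2 Mb
padding so every ±1 Mb window is fully defined. Deletion alleles are
tagged by a real SNP (carriers = dosage-2 homozygotes) so the cis scan
can find them; carriers get expression exactly 0 and a coverage-mask gap
over the gene body or the TSS. Detection dropout zeroes an observation
with probability exp(−abundance/τ) — a one-parameter monotone
level-dependence, invertible for tests. Everything is deterministic under
the seed; a replication panel can be drawn from the same frequency
surface, SNP map and planted effects with fresh accessions.

What the generator does **not** emulate: realistic recombination maps or
mutation processes, read-level noise, batch effects, tissue or
environment specificity, multi-allelic or partially penetrant structural
variants, and trans-regulatory networks. Passing tests therefore show
that the statistics are implemented correctly and behave as designed
under a plausible generative model — not that effect sizes or discovery
counts transfer to any real panel.

## Numerical choices

- Score statistics: constant phenotype or genotype yields NaN with a
  reason code, never an exception mid-scan.
- Firth fit: Newton with hat-diagonal adjustment, step-halving, 100
  iterations, tolerance 1e-8; non-convergence reports NaN with a flag.
- REML: eigenvalues clipped at 0; boundary h² = 0 preferred when its
  objective is not beaten; objective spread < 1e-8 flags a flat profile.
- Top-SNP and peak-lead ties break toward the smallest genomic position.
- Thresholds and empirical P-values: strict (<) comparisons, +1
  correction, k = floor(level·n_perm)-th smallest null min-P.
- Per-gene permutation seeds spawn from one SeedSequence; pipeline stages
  derive substreams by hashing stage names, so inserting a stage does not
  perturb the others.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data:
calibration uses 500 independent null traits on a 140-accession,
~200-SNP window with 1000 permutations each; heritability recovery uses
n = 500 with a 50-block kinship (six replicates averaged, since the
single-replicate REML spread at this design is ~0.12); recall checks use
the default panel with 120 genes. These sizes are the package's chosen
desk-scale designs; all scale linearly if enlarged.

## Known limitations

- The binary scan ignores kinship; on strongly structured panels its
  permutation null (which destroys structure) can be anticonservative
  for presence traits that track ancestry. The motivating design accepts
  this because the permutation filter targets measurement noise, not
  structure.
- The GRAMMAR+ permutation threshold avoids per-permutation REML refits;
  this is an approximation that is accurate when h² is moderate and the
  trait sample is representative.
- Fisher association treats each SV type separately; a gene with both a
  TSS and a gene-body variant is tested twice against the same presence
  vector.
- The parametric covariance-correlation P ignores the dependence of
  matrix elements; use the Mantel option for inference.
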