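"""Regional replication of discovery eQTL in a second panel.

For each discovery peak, all second-panel SNPs within +/- 10 kb of the
peak position are rescanned with the matching test (logistic score for
presence/absence traits, mmscore for quantitative traits). Replication
requires the best regional P-value to beat a Bonferroni threshold
(alpha / number of regional SNPs) and sign consistency of effects on SNPs
shared between the two panels at identical (chromosome, position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binary_scan import score_test_scan
from .datatypes import GenotypeMatrix
from .fdr import FdrReport
from .lmm import LmmFit, mmscore_scan
from .peaks import EqtlPeak

REGION_BP = 10_000


@dataclass
class ReplicationResult:
    gene_id: str
    discovery_lead_snp: str
    n_region_snps: int
    best_p: float
    region_threshold: float
    overlapping_snp_ids: list[str] = field(default_factory=list)
    sign_consistent: str = "untestable"  # yes | no | untestable
    replicated: bool = False
    reason: str | None = None


def _discovery_signs(discovery_result, g1: GenotypeMatrix) -> dict:
    out = {}
    sign = discovery_result.sign
    if sign is None:
        return out
    for local, snp in enumerate(np.asarray(discovery_result.snp_index)):
        s = sign[local]
        if np.isfinite(s) and s != 0:
            out[(str(g1.chrom[snp]), int(g1.pos[snp]))] = float(s)
    return out


def replicate(
    peak: EqtlPeak,
    phenotype2: np.ndarray | None,
    genotypes2: GenotypeMatrix,
    scan_kind: str,
    *,
    discovery_result=None,
    genotypes1: GenotypeMatrix | None = None,
    fit2: LmmFit | None = None,
    alpha: float = 0.01,
    sign_rule: str = "all",
) -> ReplicationResult:
    """Test one discovery peak in the replication panel.

    phenotype2 is the gene's binary presence vector (scan_kind='binary') or
    its rank-transformed expression (scan_kind='lmm', with `fit2` the
    polygenic fit); pass None when the gene is not expressed (variably) in
    the second panel. Sign consistency compares the per-SNP effect signs of
    the discovery scan against the replication scan on SNPs present in both
    panels at the same (chrom, pos); with sign_rule='all' every shared SNP
    must agree, 'majority' requires more than half.
    """
    if phenotype2 is None:
        return ReplicationResult(
            peak.gene_id, peak.lead_snp, 0, math.nan, math.nan,
            reason="not_expressed",
        )
    region = genotypes2.window_index(
        peak.chrom, max(1, peak.pos - REGION_BP), peak.pos + REGION_BP
    )
    if len(region) == 0:
        return ReplicationResult(
            peak.gene_id, peak.lead_snp, 0, math.nan, math.nan, reason="no_snps"
        )
    G = genotypes2.dosage[:, region]
    G = np.where(np.isnan(G), np.nanmean(G, axis=0, keepdims=True), G)
    if scan_kind == "binary":
        _, p, sign2 = score_test_scan(np.asarray(phenotype2, float), G)
    elif scan_kind == "lmm":
        if fit2 is None:
            raise ValueError("scan_kind='lmm' requires fit2")
        res2 = mmscore_scan(fit2, genotypes2, snp_index=region, gene_id=peak.gene_id)
        p, sign2 = res2.p_value, res2.sign
    else:
        raise ValueError(f"unknown scan_kind {scan_kind!r}")
    finite = np.isfinite(p)
    if not finite.any():
        return ReplicationResult(
            peak.gene_id, peak.lead_snp, len(region), math.nan,
            alpha / len(region), reason="degenerate_region",
        )
    best_p = float(np.nanmin(p[finite]))
    threshold = alpha / len(region)

    sign_state = "untestable"
    shared_ids: list[str] = []
    if discovery_result is not None and genotypes1 is not None:
        disc = _discovery_signs(discovery_result, genotypes1)
        agree, total = 0, 0
        for local, snp in enumerate(region):
            key = (str(genotypes2.chrom[snp]), int(genotypes2.pos[snp]))
            if key in disc and np.isfinite(sign2[local]) and sign2[local] != 0:
                total += 1
                shared_ids.append(genotypes2.snp_ids[snp])
                if disc[key] == sign2[local]:
                    agree += 1
        if total > 0:
            if sign_rule == "all":
                sign_state = "yes" if agree == total else "no"
            else:
                sign_state = "yes" if agree > total / 2 else "no"
    replicated = (best_p < threshold) and (sign_state == "yes")
    return ReplicationResult(
        peak.gene_id, peak.lead_snp, int(len(region)), best_p, threshold,
        shared_ids, sign_state, replicated,
    )


def replication_fdr(n_tested: int, n_replicated: int, alpha: float) -> FdrReport:
    """Empirical FDR of the replication analysis: q = alpha * T / R."""
    return FdrReport(alpha, n_tested, n_replicated)
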