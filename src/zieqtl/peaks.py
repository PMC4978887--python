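"""Collapse per-SNP association results into eQTL peaks; cis/trans labels.

Significant SNPs for a gene are merged into one peak when they lie within
1 Mb of each other (single-linkage); the peak location is the SNP with the
smallest P-value (ties broken toward the smallest position). A peak is cis
when its lead SNP lies on the gene's chromosome within 1 Mb (inclusive) of
the nearest gene-body endpoint, and trans otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, GenotypeMatrix

MERGE_GAP_BP = 1_000_000
CIS_DISTANCE_BP = 1_000_000


@dataclass
class EqtlPeak:
    gene_id: str
    lead_snp: str
    chrom: str
    pos: int
    p: float
    classification: str | None = None  # "cis" | "trans"
    distance_to_tss: float = math.nan  # signed bp; NaN on another chromosome
    n_snps: int = 1


def define_peaks(result, g: GenotypeMatrix, threshold_p: float) -> list[EqtlPeak]:
    """Merge a gene's significant SNPs into peaks.

    `result` is any scan result exposing snp_index/p_value (GwasResult or
    BinaryScanResult). Merging is per chromosome, single-linkage with gap
    <= 1 Mb (inclusive); each cluster's lead SNP is its min-P SNP.
    """
    p = np.asarray(result.p_value, dtype=float)
    sig = np.isfinite(p) & (p < threshold_p)
    if not sig.any():
        return []
    idx = np.asarray(result.snp_index)[sig]
    pv = p[sig]
    peaks = []
    for chrom in pd.unique(g.chrom[idx]):
        on = g.chrom[idx] == chrom
        ii, pp = idx[on], pv[on]
        order = np.argsort(g.pos[ii], kind="stable")
        ii, pp = ii[order], pp[order]
        pos = g.pos[ii]
        breaks = np.flatnonzero(np.diff(pos) > MERGE_GAP_BP) + 1
        for cluster, cp in zip(np.split(ii, breaks), np.split(pp, breaks)):
            mp = cp.min()
            cand = np.flatnonzero(cp <= mp)
            lead_local = cand[np.argmin(g.pos[cluster[cand]])]
            lead = int(cluster[lead_local])
            peaks.append(
                EqtlPeak(
                    result.gene_id,
                    g.snp_ids[lead],
                    str(g.chrom[lead]),
                    int(g.pos[lead]),
                    float(mp),
                    n_snps=len(cluster),
                )
            )
    peaks.sort(key=lambda pk: (pk.chrom, pk.pos))
    return peaks


def classify(peak: EqtlPeak, ann: GeneAnnotation) -> EqtlPeak:
    """Label a peak cis or trans relative to its gene.

    Cis iff same chromosome and the distance to the nearest gene-body
    endpoint is <= 1 Mb (inclusive; a position inside the gene counts as
    distance 0). The reported distance_to_tss is signed along the gene's
    strand (positive = downstream of the TSS).
    """
    info = ann.gene(peak.gene_id)
    if peak.chrom != info.chrom:
        peak.classification = "trans"
        peak.distance_to_tss = math.nan
        return peak
    if info.start <= peak.pos <= info.end:
        dist = 0
    else:
        dist = min(abs(peak.pos - info.start), abs(peak.pos - info.end))
    peak.classification = "cis" if dist <= CIS_DISTANCE_BP else "trans"
    signed = peak.pos - int(info.tss)
    peak.distance_to_tss = float(signed if info.strand == "+" else -signed)
    return peak


def peak_table(peaks: list[EqtlPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": pk.gene_id,
                "lead_snp": pk.lead_snp,
                "chrom": pk.chrom,
                "pos": pk.pos,
                "p": pk.p,
                "classification": pk.classification,
                "distance_to_tss": pk.distance_to_tss,
                "n_snps": pk.n_snps,
            }
            for pk in peaks
        ]
    )
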