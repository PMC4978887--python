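"""Putative structural variants from zero-coverage masks, and their
association with transcript presence.

A gene carries a TSS gap in an accession when the TSS base lies inside a
zero-coverage interval, and a gene-body gap when the whole [start, end]
span is contained in one merged zero-coverage run. Gaps shared by more
than `min_carriers` accessions become structural-variant calls, which are
tested against transcript presence with a two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BinaryPresenceMatrix, CoverageMask, GeneAnnotation


@dataclass
class SVCall:
    gene_id: str
    sv_type: str  # "tss_gap" | "gene_body_gap"
    carrier_accessions: list[str]

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_accessions)


def call_svs(
    masks: list[CoverageMask],
    ann: GeneAnnotation,
    min_carriers: int = 5,
    gene_ids: list[str] | None = None,
    tss_window: int = 0,
) -> list[SVCall]:
    """Call SVs where > min_carriers accessions share the same gap.

    `tss_window` widens the TSS-gap query to tss +/- w bp (default: the
    single TSS base pair). Chromosomes absent from an accession's mask are
    treated as covered.
    """
    if gene_ids is None:
        gene_ids = ann.gene_ids
    carriers: dict[tuple[str, str], list[str]] = {}
    for mask in masks:
        for gid in gene_ids:
            info = ann.gene(gid)
            tss = int(info.tss)
            if tss_window > 0:
                tss_hit = mask.contains_interval(
                    info.chrom, tss - tss_window, tss + tss_window
                )
            else:
                tss_hit = mask.covers_point(info.chrom, tss)
            if tss_hit:
                carriers.setdefault((gid, "tss_gap"), []).append(mask.accession_id)
            if mask.contains_interval(info.chrom, int(info.start), int(info.end)):
                carriers.setdefault((gid, "gene_body_gap"), []).append(
                    mask.accession_id
                )
    calls = [
        SVCall(gid, sv_type, accs)
        for (gid, sv_type), accs in sorted(carriers.items())
        if len(accs) > min_carriers
    ]
    return calls


@dataclass
class SvAssociation:
    gene_id: str
    sv_type: str
    table: np.ndarray  # [[carrier&present, carrier&absent], [non&present, non&absent]]
    fisher_p: float
    odds_ratio: float
    significant_nominal: bool
    significant_bonferroni: bool
    degenerate: bool = False


def fisher_association(
    sv: SVCall,
    b: BinaryPresenceMatrix,
    n_genes_tested: int = 1,
    alpha: float = 0.05,
) -> SvAssociation:
    """Two-sided Fisher exact test of SV carrier status vs presence.

    The odds ratio is the sample OR with a 0.5 continuity correction. When
    transcript presence is constant across accessions the test degenerates
    to p = 1 and is flagged.
    """
    present = b.gene_vector(sv.gene_id).astype(bool)
    carrier = np.isin(b.accession_ids, sv.carrier_accessions)
    a = int(np.sum(carrier & present))
    c = int(np.sum(carrier & ~present))
    d = int(np.sum(~carrier & present))
    e = int(np.sum(~carrier & ~present))
    table = np.array([[a, c], [d, e]])
    degenerate = (present.all() or (~present).all())
    if degenerate:
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    orr = (a + 0.5) * (e + 0.5) / ((c + 0.5) * (d + 0.5))
    return SvAssociation(
        sv.gene_id,
        sv.sv_type,
        table,
        float(p),
        float(orr),
        p < alpha,
        p < alpha / max(n_genes_tested, 1),
        degenerate,
    )


def associate_all(
    calls: list[SVCall], b: BinaryPresenceMatrix, alpha: float = 0.05
) -> list[SvAssociation]:
    """Fisher tests for every call, Bonferroni over the batch of SV genes."""
    n_genes = len({c.gene_id for c in calls})
    return [fisher_association(c, b, n_genes_tested=n_genes, alpha=alpha)
            for c in calls if c.gene_id in b.gene_ids]


def sv_summary(calls: list[SVCall], associations: list[SvAssociation]) -> dict:
    """Descriptive summaries of the call set.

    Per-accession counts of SV-disrupted genes, per-gene carrier counts,
    the number of genes with at least two distinct SV types, and the
    nominal / Bonferroni-significant association counts.
    """
    per_accession: dict[str, set] = {}
    per_gene: dict[str, set] = {}
    types_per_gene: dict[str, set] = {}
    for c in calls:
        types_per_gene.setdefault(c.gene_id, set()).add(c.sv_type)
        for a in c.carrier_accessions:
            per_accession.setdefault(a, set()).add(c.gene_id)
            per_gene.setdefault(c.gene_id, set()).add(a)
    acc_counts = pd.Series({a: len(s) for a, s in per_accession.items()}, dtype=int)
    gene_counts = pd.Series({g: len(s) for g, s in per_gene.items()}, dtype=int)
    return {
        "n_calls": len(calls),
        "n_sv_genes": len(types_per_gene),
        "per_accession_counts": acc_counts,
        "per_gene_carrier_counts": gene_counts,
        "mean_genes_per_accession": float(acc_counts.mean()) if len(acc_counts) else 0.0,
        "mean_carriers_per_gene": float(gene_counts.mean()) if len(gene_counts) else 0.0,
        "n_multi_type_genes": sum(1 for s in types_per_gene.values() if len(s) >= 2),
        "n_nominal_significant": sum(1 for a in associations if a.significant_nominal),
        "n_bonferroni_significant": sum(
            1 for a in associations if a.significant_bonferroni
        ),
    }
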