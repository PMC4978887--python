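"""Correlation between transcriptome and genome relationship matrices.

The presence/absence profile of the selected variable genes defines a
binary relationship matrix built with the same frequency-weighted formula
as the genomic relationship matrix; its correlation with the genomic
kinship quantifies how much transcript sharing follows genome sharing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import BinaryPresenceMatrix, ValidationError
from .lmm import KinshipMatrix


def binary_relationship(
    b: BinaryPresenceMatrix,
    gene_subset: list[str] | None = None,
    regularization: float = 0.0,
) -> KinshipMatrix:
    """Frequency-weighted relationship matrix from 0/1 presence calls.

    r_ij = (1/G) sum_g (b_ig - p_g)(b_jg - p_g) / (p_g (1 - p_g)) with p_g
    the presence frequency. Every gene in the subset must have presence
    frequency strictly inside (0, 1).
    """
    if gene_subset is None:
        gene_subset = list(b.gene_ids)
    cols = [b.gene_ids.index(g) for g in gene_subset]
    X = b.present[:, cols].astype(float)
    p = X.mean(axis=0)
    if np.any((p <= 0) | (p >= 1)):
        bad = [gene_subset[i] for i in np.flatnonzero((p <= 0) | (p >= 1))]
        raise ValidationError(
            f"genes with presence frequency 0 or 1 must be pre-filtered: {bad[:5]}"
        )
    z = (X - p) / np.sqrt(p * (1 - p))
    k = (z @ z.T) / len(cols)
    if regularization:
        k = k + regularization * np.eye(k.shape[0])
    return KinshipMatrix(list(b.accession_ids), k)


@dataclass
class MatrixCorrelation:
    r: float
    p_parametric: float
    n_pairs: int
    p_mantel: float | None = None
    mantel_perms: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_parametric": self.p_parametric,
            "n_pairs": self.n_pairs,
            "p_mantel": self.p_mantel,
            "mantel_perms": self.mantel_perms,
        }


def correlate_matrices(
    r1: KinshipMatrix,
    r2: KinshipMatrix,
    mantel_perms: int = 0,
    seed: int = 0,
) -> MatrixCorrelation:
    """Pearson correlation over strictly-upper-triangle matrix elements.

    The parametric P treats the n(n-1)/2 pairs as independent (they are
    not); the optional Mantel permutation P, which permutes accession
    labels of one matrix, is the defensible test.
    """
    if r1.accession_ids != r2.accession_ids:
        raise ValidationError("matrices must share accession ordering")
    n = len(r1.accession_ids)
    if n < 4:
        raise ValueError("need at least 4 accessions")
    iu = np.triu_indices(n, k=1)
    x, y = r1.k[iu], r2.k[iu]
    r, p = stats.pearsonr(x, y)
    p_mantel = None
    if mantel_perms > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(mantel_perms):
            perm = rng.permutation(n)
            yp = r2.k[np.ix_(perm, perm)][iu]
            rp, _ = stats.pearsonr(x, yp)
            if abs(rp) >= abs(r):
                hits += 1
        p_mantel = (1 + hits) / (1 + mantel_perms)
    return MatrixCorrelation(
        float(r), float(p), len(x), p_mantel, mantel_perms, seed
    )


def expected_excess_shared(n_genes: int, r: float) -> int:
    """Expected extra shared transcripts between clones vs unrelated lines.

    Product n_genes * r truncated toward zero (e.g. 4317 genes at r = 0.035
    gives 151).
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not -1 <= r <= 1:
        raise ValueError("r must be in [-1, 1]")
    return int(math.trunc(n_genes * r))
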