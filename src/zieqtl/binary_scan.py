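"""Presence/absence cis-eQTL mapping by logistic score tests.

For each gene a +/- 1 Mb window around the TSS is scanned with a 1-df
logistic score test of the binarized phenotype on SNP dosage. Significance
combines a Bonferroni filter over the window's SNPs with a trait-specific
threshold from a min-P permutation null (phenotype shuffling), and the
reportable effect at the top SNP is a Firth (Jeffreys-prior) penalized
log odds ratio, finite even under complete separation. Kinship is
deliberately not used here: the scan is a plain logistic association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import GeneAnnotation, GenotypeMatrix
from .fdr import FdrReport

CIS_WINDOW_BP = 1_000_000


@dataclass
class CisWindow:
    gene_id: str
    chrom: str
    lo: int
    hi: int
    snp_index: np.ndarray

    @classmethod
    def around_tss(
        cls, gene_id: str, ann: GeneAnnotation, g: GenotypeMatrix,
        span: int = CIS_WINDOW_BP,
    ) -> "CisWindow":
        info = ann.gene(gene_id)
        lo = max(1, int(info.tss) - span)
        hi = int(info.tss) + span
        return cls(gene_id, info.chrom, lo, hi, g.window_index(info.chrom, lo, hi))


# -- score test -------------------------------------------------------------

def logistic_score_test(y: np.ndarray, g: np.ndarray):
    """Intercept-only logistic score test of binary y on dosage g.

    U = sum g_i (y_i - ybar), V = ybar (1 - ybar) * sum (g_i - gbar)^2,
    statistic U^2 / V ~ chi2(1). Missing entries in either vector are
    dropped pairwise. Returns (statistic, p_value); (nan, nan) when either
    vector is constant on the complete pairs.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g = y[ok], g[ok]
    if len(y) == 0:
        return math.nan, math.nan
    ybar = y.mean()
    gc = g - g.mean()
    v = ybar * (1 - ybar) * np.dot(gc, gc)
    if v <= 0:
        return math.nan, math.nan
    u = np.dot(g, y - ybar)
    stat = u * u / v
    return float(stat), float(stats.chi2.sf(stat, 1))


def score_test_scan(y: np.ndarray, G: np.ndarray):
    """Vectorized score tests of one complete binary y against SNP columns.

    Returns (stat, p, sign) arrays; constant SNPs get nan. G must have no
    missing values (the per-gene scan falls back to the pairwise path).
    """
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    Gc = G - G.mean(axis=0, keepdims=True)
    ss = np.einsum("ij,ij->j", Gc, Gc)
    v = ybar * (1 - ybar) * ss
    u = Gc.T @ y  # sum g~ y == sum g (y - ybar) for centered g
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(v > 0, u * u / v, np.nan)
    p = np.where(np.isfinite(stat), stats.chi2.sf(stat, 1), np.nan)
    return stat, p, np.sign(u)


# -- Firth penalized logistic fit -------------------------------------------

def firth_logor(y: np.ndarray, g: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth penalized-likelihood logistic slope and its standard error.

    Fits logit P(y=1) = b0 + b1 g with the Jeffreys-prior penalty, which
    keeps the estimate finite under complete separation. Returns
    (log_or, se); (nan, nan) with no convergence.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g = y[ok], g[ok]
    X = np.column_stack([np.ones_like(g), g])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return math.nan, math.nan
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat diagonal
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving for stability on near-separated data
        for _ in range(20):
            if np.max(np.abs(step)) < 20:
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1 - p)
            info = (X.T * w) @ X
            se = math.sqrt(np.linalg.inv(info)[1, 1])
            return float(beta[1]), se
    return math.nan, math.nan


# -- per-gene scan ----------------------------------------------------------

@dataclass
class BinaryScanResult:
    gene_id: str
    snp_index: np.ndarray
    stat: np.ndarray
    p_value: np.ndarray
    top_snp: str | None
    top_index: int | None
    min_p: float
    log_or: float = math.nan
    se: float = math.nan
    n_snps: int = 0
    reason: str | None = None

    @property
    def sign(self):
        return self._sign

    _sign: np.ndarray = field(default=None, repr=False)


def _argmin_p(p: np.ndarray, pos: np.ndarray) -> int | None:
    """Index of the smallest p; ties broken by smallest genomic position."""
    finite = np.isfinite(p)
    if not finite.any():
        return None
    mp = np.nanmin(p[finite])
    cand = np.flatnonzero(finite & (p <= mp))
    return int(cand[np.argmin(pos[cand])])


def scan_gene(
    y: np.ndarray,
    window: CisWindow,
    g: GenotypeMatrix,
    fit_effect: bool = True,
) -> BinaryScanResult:
    """Score-test every SNP in the cis window; Firth effect at the top SNP."""
    if len(window.snp_index) == 0:
        return BinaryScanResult(
            window.gene_id, window.snp_index, np.array([]), np.array([]),
            None, None, math.nan, reason="empty_window",
        )
    G = g.dosage[:, window.snp_index]
    y = np.asarray(y, dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2:
        return BinaryScanResult(
            window.gene_id, window.snp_index, np.array([]), np.array([]),
            None, None, math.nan, reason="constant_phenotype",
        )
    if np.isnan(G).any() or np.isnan(y).any():
        out = [logistic_score_test(y, G[:, j]) for j in range(G.shape[1])]
        stat = np.array([s for s, _ in out])
        p = np.array([q for _, q in out])
        sign = np.full(len(stat), np.nan)
    else:
        stat, p, sign = score_test_scan(y, G)
    local = _argmin_p(p, g.pos[window.snp_index])
    res = BinaryScanResult(
        window.gene_id,
        window.snp_index,
        stat,
        p,
        g.snp_ids[window.snp_index[local]] if local is not None else None,
        int(window.snp_index[local]) if local is not None else None,
        float(np.nanmin(p)) if local is not None else math.nan,
        n_snps=len(window.snp_index),
        _sign=sign,
    )
    if fit_effect and res.top_index is not None:
        res.log_or, res.se = firth_logor(y, g.dosage[:, res.top_index])
    return res


# -- permutation null -------------------------------------------------------

@dataclass
class PermutationNull:
    gene_id: str
    minp_null: np.ndarray
    level: float
    threshold: float
    empirical_p: float
    seed: int


def permutation_null(
    y: np.ndarray,
    window: CisWindow,
    g: GenotypeMatrix,
    n_perm: int = 1000,
    level: float = 0.01,
    seed: int = 0,
    observed_min_p: float | None = None,
) -> PermutationNull:
    """Min-P null from shuffling the binary phenotype against cis genotypes.

    The trait-specific threshold is the floor(level * n_perm)-th smallest
    null min-P; the empirical P carries the +1 correction so it is never 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(y, dtype=float)
    G = g.dosage[:, window.snp_index]
    ok = ~np.isnan(y)
    y, G = y[ok], G[ok, :]
    G = np.where(np.isnan(G), np.nanmean(G, axis=0, keepdims=True), G)
    rng = np.random.default_rng(seed)
    n = len(y)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):  # Fisher-Yates via Generator.permutation
        perms[i] = y[rng.permutation(n)]
    ybar = y.mean()
    Gc = G - G.mean(axis=0, keepdims=True)
    v = ybar * (1 - ybar) * np.einsum("ij,ij->j", Gc, Gc)
    good = v > 0
    U = perms @ Gc[:, good]  # (n_perm, S)
    stat_max = (U * U / v[good]).max(axis=1)
    minp = stats.chi2.sf(stat_max, 1)
    if observed_min_p is None:
        obs_stat, _, _ = score_test_scan(y, G[:, good])
        observed_min_p = float(stats.chi2.sf(np.nanmax(obs_stat), 1))
    k = int(math.floor(level * n_perm))
    srt = np.sort(minp)
    threshold = float(srt[max(k - 1, 0)]) if k >= 1 else 0.0
    emp = (1 + int(np.sum(minp <= observed_min_p))) / (1 + n_perm)
    return PermutationNull(window.gene_id, minp, level, threshold, emp, seed)


# -- discovery --------------------------------------------------------------

@dataclass
class BinaryDiscovery:
    results: dict
    nulls: dict
    significant_genes: list[str]
    fdr: FdrReport


def discover(
    b,
    genotypes: GenotypeMatrix,
    ann: GeneAnnotation,
    gene_ids: list[str],
    *,
    level: float = 0.01,
    bonferroni_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> BinaryDiscovery:
    """Scan, permute and threshold every selected gene.

    A gene is significant iff its min-P beats both the window Bonferroni
    bound (bonferroni_alpha / n_snps) and its trait-specific permutation
    threshold at `level`. The FDR report uses q = level * T / R.
    """
    ss = np.random.SeedSequence(seed)
    gene_seeds = {
        gid: int(child.generate_state(1)[0] % (2**31))
        for gid, child in zip(gene_ids, ss.spawn(len(gene_ids)))
    }
    results, nulls, significant = {}, {}, []
    for gid in gene_ids:
        y = b.gene_vector(gid).astype(float)
        window = CisWindow.around_tss(gid, ann, genotypes)
        res = scan_gene(y, window, genotypes)
        results[gid] = res
        if res.top_index is None:
            continue
        null = permutation_null(
            y, window, genotypes, n_perm=n_perm, level=level,
            seed=gene_seeds[gid], observed_min_p=res.min_p,
        )
        nulls[gid] = null
        bonf = bonferroni_alpha / res.n_snps
        if res.min_p < bonf and res.min_p < null.threshold:
            significant.append(gid)
    fdr = FdrReport(level, len(gene_ids), len(significant))
    return BinaryDiscovery(results, nulls, significant, fdr)
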