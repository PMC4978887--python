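"""Kinship-corrected quantitative eQTL scans.

The phenotype model is y = X b + u + e with u ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I), where K is the frequency-weighted (VanRaden-type)
genomic relationship matrix. The polygenic fit is a one-dimensional REML
over h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) on the eigenbasis of K;
per-SNP association uses the mmscore statistic
T = (g~' V^-1 y~)^2 / (g~' V^-1 g~) against chi2(1). Genome-wide
significance is set by pooling min-P values from naive score scans of
permuted GRAMMAR+ residuals (no per-permutation REML refit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, ValidationError
from .fdr import FdrReport


@dataclass
class KinshipMatrix:
    accession_ids: list[str]
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if self.k.shape != (len(self.accession_ids),) * 2:
            raise ValidationError("kinship shape mismatch")


def grm_freq(g: GenotypeMatrix, regularization: float = 1e-8) -> KinshipMatrix:
    """Frequency-weighted genomic relationship matrix.

    k_ij = (1/M) sum_m (g_im - 2 p_m)(g_jm - 2 p_m) / (2 p_m (1 - p_m))
    with p_m the sample allele frequency; missing dosages are mean-imputed
    per SNP, and `regularization` is added to the diagonal for PSD
    stability. Rows sum to exactly zero pre-regularization.
    """
    d = g.dosage.copy()
    mu = np.nanmean(d, axis=0)
    nan = np.isnan(d)
    if nan.any():
        d[nan] = np.broadcast_to(mu, d.shape)[nan]
    p = mu / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("monomorphic SNP in GRM input; run QC first")
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    k = (z @ z.T) / g.n_snps
    if regularization:
        k = k + regularization * np.eye(k.shape[0])
    return KinshipMatrix(list(g.accession_ids), k)


def rank_inverse_normal(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5)/n).

    Ties get average ranks. Raises on a constant vector.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("constant vector cannot be rank-transformed")
    r = stats.rankdata(y, method="average")
    return stats.norm.ppf((r - 0.5) / len(y))


@dataclass
class LmmFit:
    accession_ids: list[str]
    y: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    beta0: float
    eigvals: np.ndarray = field(repr=False)
    eigvecs: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    grammar_plus_residuals: np.ndarray = field(repr=False)
    flat_objective: bool = False

    def vinv(self, x: np.ndarray) -> np.ndarray:
        """V^-1 x with V = sigma_g2 K + sigma_e2 I via the stored eigenbasis."""
        w = self.sigma_g2 * self.eigvals + self.sigma_e2
        return self.eigvecs @ ((self.eigvecs.T @ x) / w)


def _reml_loglik(h2: float, lam: np.ndarray, ystar: np.ndarray, xstar: np.ndarray):
    w = h2 * lam + (1 - h2)
    w = np.maximum(w, 1e-12)
    xtwx = np.sum(xstar * xstar / w)
    beta = np.sum(xstar * ystar / w) / xtwx
    resid = ystar - xstar * beta
    rss = np.sum(resid * resid / w)
    n = len(ystar)
    s2 = rss / (n - 1)
    ll = -0.5 * ((n - 1) * math.log(s2) + np.sum(np.log(w)) + math.log(xtwx))
    return ll, beta, s2


def fit_polygenic(
    y: np.ndarray,
    K: KinshipMatrix,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> LmmFit:
    """Intercept-only REML fit of the polygenic model over h2 in [0, 1].

    One eigendecomposition of K (pass `eig` to reuse it across genes)
    reduces REML to a 1-d profile likelihood, maximized by a coarse grid
    plus bounded refinement. A flat objective (e.g. K = I) returns h2 = 0
    with `flat_objective` set. GRAMMAR+ residuals V^-1 (y - X beta),
    standardized to unit variance, are stored for permutation scans.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if eig is None:
        lam, U = np.linalg.eigh(K.k)
    else:
        lam, U = eig
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite eigenvalues: kinship matrix ill-conditioned")
    lam = np.maximum(lam, 0.0)
    ystar = U.T @ y
    xstar = U.T @ np.ones(n)

    grid = np.linspace(0.0, 0.999, 25)
    lls = np.array([_reml_loglik(h, lam, ystar, xstar)[0] for h in grid])
    if not np.all(np.isfinite(lls)):
        raise ValueError("non-finite REML objective: check kinship conditioning")
    flat = np.ptp(lls) < 1e-8
    if flat:
        h2 = 0.0
    else:
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        opt = optimize.minimize_scalar(
            lambda h: -_reml_loglik(h, lam, ystar, xstar)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        h2 = float(opt.x)
        if _reml_loglik(0.0, lam, ystar, xstar)[0] >= -opt.fun:
            h2 = 0.0
    ll, beta, s2 = _reml_loglik(h2, lam, ystar, xstar)
    sigma_g2 = h2 * s2
    sigma_e2 = (1 - h2) * s2
    resid = y - beta
    w = sigma_g2 * lam + sigma_e2
    r = U @ ((U.T @ resid) / w)
    r_sd = r.std()
    r_std = (r - r.mean()) / r_sd if r_sd > 0 else r
    return LmmFit(
        list(K.accession_ids), y, sigma_g2, sigma_e2, h2, float(beta),
        lam, U, resid, r_std, flat_objective=bool(flat),
    )


# -- association scan -------------------------------------------------------

@dataclass
class GwasResult:
    gene_id: str
    snp_index: np.ndarray
    stat: np.ndarray
    p_value: np.ndarray
    sign: np.ndarray
    top_snp: str | None
    top_index: int | None
    min_p: float


def mmscore_scan(
    fit: LmmFit,
    g: GenotypeMatrix,
    snp_index: np.ndarray | None = None,
    gene_id: str = "",
) -> GwasResult:
    """Mixed-model score test per SNP on the fitted null model.

    T = (g~' V^-1 y~)^2 / (g~' V^-1 g~), with g~ the centered dosage and
    y~ the phenotype minus the fitted intercept; reduces to the ordinary
    linear score test when h2 = 0. Constant SNPs yield NaN.
    """
    if snp_index is None:
        snp_index = np.arange(g.n_snps)
    snp_index = np.asarray(snp_index)
    G = g.dosage[:, snp_index]
    G = np.where(np.isnan(G), np.nanmean(G, axis=0, keepdims=True), G)
    Gc = G - G.mean(axis=0, keepdims=True)
    vy = fit.vinv(fit.residuals)
    num = Gc.T @ vy
    w = fit.sigma_g2 * fit.eigvals + fit.sigma_e2
    B = fit.eigvecs.T @ Gc
    den = np.einsum("ij,ij->j", B, B / w[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 1e-12, num * num / den, np.nan)
    p = np.where(np.isfinite(stat), stats.chi2.sf(stat, 1), np.nan)
    finite = np.isfinite(p)
    if finite.any():
        mp = np.nanmin(p[finite])
        cand = np.flatnonzero(finite & (p <= mp))
        local = int(cand[np.argmin(g.pos[snp_index[cand]])])
        top_snp = g.snp_ids[snp_index[local]]
        top_index = int(snp_index[local])
        min_p = float(mp)
    else:
        top_snp, top_index, min_p = None, None, math.nan
    return GwasResult(
        gene_id, snp_index, stat, p, np.sign(num), top_snp, top_index, min_p
    )


def naive_score_scan_stats(r: np.ndarray, Gc: np.ndarray, ss: np.ndarray):
    """chi2(1) naive score statistics of phenotype r on centered SNPs."""
    var = r.var()
    u = Gc.T @ (r - r.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ss > 0, u * u / (ss * var), np.nan)


@dataclass
class ThresholdReport:
    threshold_neglog10: float
    threshold_p: float
    level: float
    n_perm_total: int
    n_traits_used: int
    trait_ids: list[str]
    seed: int


def genome_wide_threshold(
    fits: dict[str, LmmFit],
    scans: dict[str, GwasResult],
    g: GenotypeMatrix,
    *,
    prescreen_p: float = 1e-6,
    n_traits_sample: int = 200,
    n_perm: int = 200,
    level: float = 0.01,
    seed: int = 0,
) -> ThresholdReport:
    """Pooled min-P permutation threshold from GRAMMAR+ residual scans.

    Traits with at least one SNP below `prescreen_p` are eligible; up to
    `n_traits_sample` of them are drawn without replacement, each permuted
    `n_perm` times, and the pooled null min-P distribution's level-quantile
    sets the genome-wide threshold (reported on the -log10 scale).
    """
    eligible = [gid for gid, s in scans.items() if s.min_p < prescreen_p]
    if not eligible:
        raise ValueError(f"no trait passes the prescreen at p < {prescreen_p}")
    rng = np.random.default_rng(seed)
    take = min(n_traits_sample, len(eligible))
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=take, replace=False)]
    G = g.dosage
    G = np.where(np.isnan(G), np.nanmean(G, axis=0, keepdims=True), G)
    Gc = G - G.mean(axis=0, keepdims=True)
    ss = np.einsum("ij,ij->j", Gc, Gc)
    good = ss > 0
    Gc, ss = Gc[:, good], ss[good]
    n = Gc.shape[0]
    pool = []
    for gid in chosen:
        r = fits[gid].grammar_plus_residuals
        perms = np.empty((n_perm, n))
        for i in range(n_perm):
            perms[i] = r[rng.permutation(n)]
        perms = perms - perms.mean(axis=1, keepdims=True)
        var = perms.var(axis=1)
        U = perms @ Gc
        stat_max = ((U * U) / ss).max(axis=1) / var
        pool.append(stats.chi2.sf(stat_max, 1))
    pool = np.concatenate(pool)
    k = int(math.floor(level * len(pool)))
    srt = np.sort(pool)
    thr_p = float(srt[max(k - 1, 0)]) if k >= 1 else float(srt[0])
    return ThresholdReport(
        float(-math.log10(thr_p)), thr_p, level, len(pool), take, chosen, seed
    )


@dataclass
class StandardDiscovery:
    scans: dict[str, GwasResult]
    fits: dict[str, LmmFit]
    threshold: ThresholdReport
    significant_genes: list[str]
    fdr: FdrReport


def standard_discover(
    e,
    genotypes: GenotypeMatrix,
    gene_ids: list[str],
    *,
    kinship: KinshipMatrix | None = None,
    level: float = 0.01,
    prescreen_p: float = 1e-6,
    n_traits_sample: int = 200,
    n_perm: int = 200,
    seed: int = 0,
) -> StandardDiscovery:
    """Genome-wide mixed-model eQTL discovery for widely expressed genes.

    Each gene's expression is rank-inverse-normal transformed, fitted with
    the polygenic model (one shared eigendecomposition of K) and scanned
    genome-wide with mmscore; significance uses the pooled permutation
    threshold and the FDR report is q = level * T / R.
    """
    if kinship is None:
        kinship = grm_freq(genotypes)
    eig = np.linalg.eigh(kinship.k)
    fits, scans = {}, {}
    for gid in gene_ids:
        y = rank_inverse_normal(e.gene_vector(gid))
        fit = fit_polygenic(y, kinship, eig=eig)
        fits[gid] = fit
        scans[gid] = mmscore_scan(fit, genotypes, gene_id=gid)
    threshold = genome_wide_threshold(
        fits, scans, genotypes,
        prescreen_p=prescreen_p, n_traits_sample=n_traits_sample,
        n_perm=n_perm, level=level, seed=seed,
    )
    significant = [gid for gid in gene_ids if scans[gid].min_p < threshold.threshold_p]
    fdr = FdrReport(level, len(gene_ids), len(significant))
    return StandardDiscovery(scans, fits, threshold, significant, fdr)
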