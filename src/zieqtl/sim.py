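"""Synthetic genotype/expression datasets with known ground truth.

The generator emulates a panel of naturally inbred accessions: population
structure via the Balding-Nichols model, linkage disequilibrium in blocks,
log-normal baseline expression with a polygenic component, planted additive
and presence/absence cis effects, deletion alleles that simultaneously zero
expression and punch holes in the per-accession coverage masks, and a
detection-dropout process whose rate decays with true abundance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .datatypes import (
    CoverageMask,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    ValidationError,
)

import pandas as pd


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults describe a desk-scale version of a worldwide inbred accession
    panel: 140 accessions in 3 subpopulations at Fst 0.2, two 12-Mb
    chromosomes with 2000 SNPs each in 100-kb LD blocks, and 60 genes of
    which 20% carry an additive cis effect, 20% a presence/absence cis
    effect (log-odds 3 across the dosage range) and 10% a deletion allele.
    """

    n_accessions: int = 140
    n_subpops: int = 3
    fst: float = 0.2
    n_chrom: int = 2
    snps_per_chrom: int = 2000
    chrom_length: int = 12_000_000
    ld_block_span: int = 100_000
    ld_leak: float = 0.1  # per-SNP probability of escaping its block haplotype
    inbred: bool = True
    missing_rate: float = 0.0
    n_genes: int = 60
    frac_presence_genes: float = 0.2
    frac_additive_genes: float = 0.2
    frac_sv_genes: float = 0.1
    effect_size_logor: float = 3.0
    effect_size_beta: float = 1.0
    h2_polygenic: float = 0.3
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.5
    residual_log_sd: float = 1.0
    dropout_tau: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst < 1):
            raise ConfigError("fst must be in (0, 1)")
        for name in ("frac_presence_genes", "frac_additive_genes", "frac_sv_genes"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.dropout_tau < 0:
            raise ConfigError("dropout_tau must be >= 0")


@dataclass
class SyntheticTruth:
    """Per-gene record of planted effects.

    Each record: gene_id, causal_snp_id (or None), effect_type in
    {none, additive, presence, sv_deletion}, true_effect, carrier_accessions
    (deletion genes only) and sv_type for deletion genes.
    """

    records: list[dict] = field(default_factory=list)

    def by_type(self, effect_type: str) -> list[dict]:
        return [r for r in self.records if r["effect_type"] == effect_type]

    def gene_record(self, gene_id: str) -> dict:
        for r in self.records:
            if r["gene_id"] == gene_id:
                return r
        raise KeyError(gene_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(json.load(fh))


# -- genotypes --------------------------------------------------------------

@dataclass
class _FreqModel:
    """Balding-Nichols frequency surface shared between simulated panels."""

    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: list[str]
    f_subpop: np.ndarray  # (n_subpops, n_snps)
    block_id: np.ndarray  # per-SNP LD block index


def _make_freq_model(config: SimConfig, rng: np.random.Generator) -> _FreqModel:
    chroms, poss = [], []
    for c in range(1, config.n_chrom + 1):
        # oversample, deduplicate, trim: memory-light unique positions
        cand = rng.integers(1, config.chrom_length + 1, size=config.snps_per_chrom * 2)
        pos = np.unique(cand)[: config.snps_per_chrom]
        if len(pos) < config.snps_per_chrom:
            raise ConfigError("chromosome too short for requested SNP count")
        chroms.append(np.full(len(pos), f"chr{c}", dtype=object))
        poss.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    snp_ids = [f"{c}_{p}" for c, p in zip(chrom, pos)]
    m = len(pos)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    F = config.fst
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    f = rng.beta(a, b, size=(config.n_subpops, m))
    # block index unique across chromosomes
    chrom_codes = pd.factorize(chrom)[0]
    block = chrom_codes * (config.chrom_length // config.ld_block_span + 2) + (
        pos // config.ld_block_span
    )
    _, block_id = np.unique(block, return_inverse=True)
    return _FreqModel(chrom, pos, snp_ids, f, block_id)


def _draw_panel(
    model: _FreqModel,
    config: SimConfig,
    rng: np.random.Generator,
    prefix: str = "acc",
) -> GenotypeMatrix:
    n = config.n_accessions
    m = len(model.pos)
    subpop = np.arange(n) % config.n_subpops
    n_blocks = model.block_id.max() + 1
    # comonotone coupling: one uniform per (accession, block), with a per-SNP
    # leak to a fresh uniform; marginals stay exactly Balding-Nichols
    u_block = rng.random((n, n_blocks))
    u = u_block[:, model.block_id]
    leak = rng.random((n, m)) < config.ld_leak
    u = np.where(leak, rng.random((n, m)), u)
    thresholds = model.f_subpop[subpop, :]
    allele = u < thresholds
    if config.inbred:
        dosage = 2.0 * allele
    else:
        allele2 = rng.random((n, m)) < thresholds
        dosage = allele.astype(float) + allele2
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosage = dosage.astype(float)
        dosage[miss] = np.nan
    accession_ids = [f"{prefix}{i:03d}" for i in range(n)]
    return GenotypeMatrix(accession_ids, model.snp_ids, model.chrom, model.pos, dosage)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate an inbred accession panel under the Balding-Nichols model."""
    rng = np.random.default_rng([config.seed, 1])
    model = _make_freq_model(config, rng)
    return _draw_panel(model, config, np.random.default_rng([config.seed, 2]))


def simulate_annotation(config: SimConfig) -> GeneAnnotation:
    """Place genes uniformly with >= 2 Mb padding from chromosome ends."""
    rng = np.random.default_rng([config.seed, 7])
    pad = 2_000_000
    if config.chrom_length <= 2 * pad:
        raise ConfigError("chromosome too short for 2 Mb gene padding")
    rows = []
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    for c in range(1, config.n_chrom + 1):
        k = per_chrom[c - 1]
        starts = np.sort(rng.integers(pad, config.chrom_length - pad, size=k))
        lengths = rng.integers(1000, 5001, size=k)
        strands = rng.choice(["+", "-"], size=k)
        for j, (s, ln, st) in enumerate(zip(starts, lengths, strands)):
            rows.append((f"gene_c{c}_{j:04d}", f"chr{c}", int(s), int(s + ln), st))
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    return GeneAnnotation(df)


# -- expression -------------------------------------------------------------

def _pick_causal_snp(
    g: GenotypeMatrix, chrom: str, tss: int, rng: np.random.Generator,
    want_carriers: tuple[int, int] | None = None,
) -> int | None:
    idx = g.window_index(chrom, max(1, tss - 1_000_000), tss + 1_000_000)
    if len(idx) == 0:
        return None
    if want_carriers is not None:
        lo, hi = want_carriers
        carr = np.nansum(g.dosage[:, idx] == 2, axis=0)
        ok = idx[(carr >= lo) & (carr <= hi)]
    else:
        ok = idx[g.maf[idx] >= 0.15]
    if len(ok) == 0:
        ok = idx[g.maf[idx] > 0]
        if len(ok) == 0:
            return None
    return int(rng.choice(ok))


def simulate_expression(
    g: GenotypeMatrix,
    ann: GeneAnnotation,
    config: SimConfig,
    *,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate expression, coverage masks and ground truth for one panel.

    Passing an existing `truth` reuses the planted gene assignments and
    effect sizes (for a replication panel sharing the SNP map) while drawing
    fresh noise, presence outcomes and deletion carriers.

    Returns (ExpressionMatrix, list of CoverageMask, SyntheticTruth).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 11])
    n = g.n_accessions
    gene_ids = ann.gene_ids
    n_genes = len(gene_ids)
    n_pres = round(config.frac_presence_genes * n_genes)
    n_sv = round(config.frac_sv_genes * n_genes)
    n_add = round(config.frac_additive_genes * n_genes)
    if n_pres + n_sv + n_add > n_genes:
        raise ConfigError("more planted genes requested than genes available")

    if truth is None:
        order = list(rng.permutation(n_genes))
        assign: dict[str, dict] = {}
        cursor = 0
        for effect_type, count, effect in (
            ("presence", n_pres, config.effect_size_logor),
            ("sv_deletion", n_sv, None),
            ("additive", n_add, config.effect_size_beta),
        ):
            for k in order[cursor : cursor + count]:
                assign[gene_ids[k]] = {"effect_type": effect_type, "true_effect": effect}
            cursor += count
        for k in order[cursor:]:
            assign[gene_ids[k]] = {"effect_type": "none", "true_effect": None}
        base_mu = {
            gid: float(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
            for gid in gene_ids
        }
    else:
        assign = {
            r["gene_id"]: {
                "effect_type": r["effect_type"],
                "true_effect": r["true_effect"],
                "causal_snp_id": r.get("causal_snp_id"),
                "sv_type": r.get("sv_type"),
                "baseline_log_mean": r.get("baseline_log_mean"),
            }
            for r in truth.records
        }
        base_mu = {
            gid: assign[gid].get("baseline_log_mean", config.baseline_log_mean)
            for gid in gene_ids
        }

    # kinship-structured polygenic component
    from .lmm import grm_freq

    poly_L = None
    if config.h2_polygenic > 0:
        keep = np.flatnonzero(g.compute_maf() > 0.01)
        K = grm_freq(g.take_snps(keep)).k
        K = K / np.mean(np.diag(K))
        poly_L = np.linalg.cholesky(K + 1e-6 * np.eye(n))

    sd = config.residual_log_sd
    h2 = config.h2_polygenic
    values = np.zeros((n, n_genes))
    mask_tuples: dict[str, list] = {a: [] for a in g.accession_ids}
    records = []
    for j, gid in enumerate(gene_ids):
        info = ann.gene(gid)
        spec_j = assign[gid]
        etype = spec_j["effect_type"]
        mu = base_mu[gid]
        x = np.full(n, mu)
        if poly_L is not None:
            x = x + np.sqrt(h2) * sd * (poly_L @ rng.standard_normal(n))
        x = x + np.sqrt(max(0.0, 1 - h2)) * sd * rng.standard_normal(n)

        causal_idx = None
        carrier_ids: list[str] = []
        sv_type = None
        if etype in ("presence", "additive"):
            prior = spec_j.get("causal_snp_id")
            if prior is not None:
                try:
                    causal_idx = g.snp_index(prior)
                except KeyError:
                    causal_idx = None
            if causal_idx is None:
                causal_idx = _pick_causal_snp(g, info.chrom, int(info.tss), rng)
        elif etype == "sv_deletion":
            lo = 6
            hi = max(lo + 1, n // 3)
            causal_idx = _pick_causal_snp(
                g, info.chrom, int(info.tss), rng, want_carriers=(lo, hi)
            )
            sv_type = spec_j.get("sv_type") or str(
                rng.choice(["gene_body_gap", "tss_gap"])
            )

        if etype == "additive" and causal_idx is not None:
            dos = np.nan_to_num(g.dosage[:, causal_idx])
            x = x + float(spec_j["true_effect"]) * sd * dos / 2.0

        abundance = np.exp(x)

        if etype == "presence" and causal_idx is not None:
            dos = np.nan_to_num(g.dosage[:, causal_idx])
            b = float(spec_j["true_effect"]) / 2.0
            a = -b * float(np.mean(dos))
            present = rng.random(n) < expit(a + b * dos)
            abundance = abundance * present

        if etype == "sv_deletion" and causal_idx is not None:
            carriers = np.nan_to_num(g.dosage[:, causal_idx]) == 2
            abundance[carriers] = 0.0
            if sv_type == "gene_body_gap":
                iv = (info.chrom, int(info.start), int(info.end))
            else:
                iv = (info.chrom, int(info.tss) - 250, int(info.tss) + 250)
            carrier_ids = [g.accession_ids[i] for i in np.flatnonzero(carriers)]
            for a_id in carrier_ids:
                mask_tuples[a_id].append(iv)

        if config.dropout_tau > 0:
            p_drop = np.exp(-abundance / config.dropout_tau)
            abundance = np.where(rng.random(n) < p_drop, 0.0, abundance)

        values[:, j] = abundance
        records.append(
            {
                "gene_id": gid,
                "causal_snp_id": (
                    g.snp_ids[causal_idx] if causal_idx is not None else None
                ),
                "effect_type": etype if causal_idx is not None or etype == "none"
                else "none",
                "true_effect": spec_j["true_effect"] if causal_idx is not None else None,
                "carrier_accessions": carrier_ids,
                "sv_type": sv_type if causal_idx is not None else None,
                "baseline_log_mean": mu,
            }
        )

    expr = ExpressionMatrix(g.accession_ids, gene_ids, values)
    masks = [
        CoverageMask.from_tuples(a, tuples) if tuples else CoverageMask(a, {})
        for a, tuples in mask_tuples.items()
    ]
    return expr, masks, SyntheticTruth(records)


# -- convenience bundles ----------------------------------------------------

@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    annotation: GeneAnnotation
    masks: list[CoverageMask]
    truth: SyntheticTruth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full deterministic discovery panel from one config/seed."""
    g = simulate_genotypes(config)
    ann = simulate_annotation(config)
    e, masks, truth = simulate_expression(g, ann, config)
    return SimulatedDataset(g, e, ann, masks, truth)


def simulate_replication_dataset(
    config: SimConfig, truth: SyntheticTruth, seed: int
) -> SimulatedDataset:
    """Second panel sharing the SNP map, annotation and planted effects.

    Fresh accessions are drawn from the same Balding-Nichols frequency
    surface, so SNP coordinates coincide with the discovery panel and
    replication sign-consistency can be evaluated on shared markers.
    """
    rng_model = np.random.default_rng([config.seed, 1])
    model = _make_freq_model(config, rng_model)
    g2 = _draw_panel(model, config, np.random.default_rng([seed, 3]), prefix="rep")
    ann = simulate_annotation(config)
    e2, masks2, truth2 = simulate_expression(
        g2, ann, config, truth=truth, rng=np.random.default_rng([seed, 11])
    )
    return SimulatedDataset(g2, e2, ann, masks2, truth2)


def write_dataset(outdir, ds: SimulatedDataset, force: bool = False) -> None:
    """Write all artifacts as plain text; round-trips losslessly via zieqtl.io."""
    from . import io as zio

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (pass force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    zio.write_genotypes_tsv(ds.genotypes, outdir / "genotypes.tsv")
    zio.write_expression_tsv(ds.expression, outdir / "expression.tsv")
    zio.write_annotation_gff3(ds.annotation, outdir / "annotation.gff3")
    zio.write_masks(ds.masks, outdir / "masks")
    ds.truth.to_json(outdir / "truth.json")


def load_dataset(outdir) -> SimulatedDataset:
    from . import io as zio

    outdir = Path(outdir)
    return SimulatedDataset(
        zio.load_genotypes(outdir / "genotypes.tsv", format="tsv"),
        zio.load_expression(outdir / "expression.tsv"),
        zio.load_annotation(outdir / "annotation.gff3"),
        zio.load_coverage_masks(outdir / "masks"),
        SyntheticTruth.from_json(outdir / "truth.json"),
    )
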