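"""End-to-end orchestration of the eQTL analysis stages.

A single config (YAML-serializable) drives: simulate -> qc -> select ->
scan-binary -> scan-lmm -> peaks -> replicate -> covcor -> sv -> report.
Each stage writes TSV/JSON artifacts under the output directory and the
final report aggregates counts, FDR reports, the covariance correlation
and (for synthetic runs) truth-based recall. The global seed is expanded
into independent per-stage substreams by hashing stage names, so adding
or removing a stage does not perturb the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binary_scan, covcor, io as zio, lmm, peaks as peaks_mod, replication, sv as sv_mod
from .datatypes import ValidationError
from .selection import binarize, detection_summaries, select_variable_genes
from .sim import SimConfig, simulate_dataset, simulate_replication_dataset, write_dataset

log = logging.getLogger("zieqtl")

ALL_STAGES = [
    "simulate", "qc", "select", "scan-binary", "scan-lmm",
    "peaks", "replicate", "covcor", "sv", "report",
]


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    outdir: str = "zieqtl_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    inputs: dict = field(default_factory=dict)  # genotypes/expression/annotation/masks
    qc: dict = field(default_factory=lambda: {"maf_min": 0.05, "callrate_min": 0.95})
    select: dict = field(default_factory=lambda: {"lower_frac": 0.10, "upper_frac": 0.90})
    scan_binary: dict = field(
        default_factory=lambda: {"level": 0.01, "bonferroni_alpha": 0.05, "n_perm": 1000}
    )
    scan_lmm: dict = field(
        default_factory=lambda: {
            "level": 0.01, "prescreen_p": 1e-6, "n_traits_sample": 200,
            "n_perm": 200, "presence_frac": 0.90,
        }
    )
    replicate: dict = field(default_factory=lambda: {"alpha": 0.01, "sign_rule": "all"})
    covcor: dict = field(default_factory=lambda: {"mantel_perms": 0})
    sv: dict = field(default_factory=lambda: {"min_carriers": 5, "alpha": 0.05})

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValidationError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        _check_keys(raw, {f.name for f in dataclasses.fields(cls)}, "pipeline config")
        base = cls()
        for key in ("qc", "select", "scan_binary", "scan_lmm", "replicate", "covcor", "sv"):
            if key in raw:
                _check_keys(raw[key], set(getattr(base, key)), key)
                merged = dict(getattr(base, key))
                merged.update(raw[key])
                raw[key] = merged
        if "simulate" in raw:
            _check_keys(
                raw["simulate"],
                {f.name for f in dataclasses.fields(SimConfig)},
                "simulate",
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream below 2^31."""
    return (seed + zlib.crc32(stage.encode())) % (2**31)


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the final report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("[stage %s] starting", stage)
        try:
            _STAGE_FUNCS[stage](config, state, report, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return report


# -- stage implementations --------------------------------------------------

def _stage_simulate(config, state, report, outdir):
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
    sc = SimConfig(**sim_kwargs)
    ds = simulate_dataset(sc)
    write_dataset(outdir / "data", ds, force=True)
    state["sim_config"] = sc
    state["dataset"] = ds
    report["simulate"] = {
        "n_accessions": sc.n_accessions,
        "n_snps": ds.genotypes.n_snps,
        "n_genes": len(ds.annotation.gene_ids),
    }


def _load_inputs(config, state):
    if "dataset" in state:
        return
    inp = config.inputs
    from .sim import SimulatedDataset, SyntheticTruth

    state["dataset"] = SimulatedDataset(
        zio.load_genotypes(inp["genotypes"]),
        zio.load_expression(inp["expression"]),
        zio.load_annotation(inp["annotation"]),
        zio.load_coverage_masks(inp["masks"]) if inp.get("masks") else [],
        SyntheticTruth([]),
    )


def _stage_qc(config, state, report, outdir):
    _load_inputs(config, state)
    ds = state["dataset"]
    g = zio.filter_genotypes(ds.genotypes, **config.qc)
    e = zio.filter_accessions_by_transcript_callrate(ds.expression, mode="robust")
    if e.accession_ids != ds.genotypes.accession_ids:
        g = g.take_accessions(e.accession_ids)
    state["genotypes"] = g
    state["expression"] = e
    report["qc"] = {
        "n_snps_kept": g.n_snps,
        "n_snps_input": ds.genotypes.n_snps,
        "n_accessions_kept": e.n_accessions,
    }


def _require(state, key, stage, needed):
    if key not in state:
        raise RuntimeError(f"stage {stage!r} requires stage {needed!r} first")


def _stage_select(config, state, report, outdir):
    _require(state, "expression", "select", "qc")
    e = state["expression"]
    b = binarize(e)
    sel = select_variable_genes(e, b, **config.select)
    det = detection_summaries(e)
    state["presence"] = b
    state["selection"] = sel
    sel.to_frame().to_csv(outdir / "selection.tsv", sep="\t")
    det["per_accession"].to_csv(outdir / "detection_per_accession.tsv", sep="\t")
    det["per_gene"].to_csv(outdir / "detection_per_gene.tsv", sep="\t")
    report["select"] = {
        "n_selected": len(sel.selected_gene_ids),
        "level_threshold": sel.level_threshold,
        "detection_spearman_rho": det["spearman_rho"],
    }


def _stage_scan_binary(config, state, report, outdir):
    _require(state, "selection", "scan-binary", "select")
    ds = state["dataset"]
    disc = binary_scan.discover(
        state["presence"], state["genotypes"], ds.annotation,
        state["selection"].selected_gene_ids,
        seed=stage_seed(config.seed, "scan-binary"),
        **config.scan_binary,
    )
    state["binary_discovery"] = disc
    rows = []
    for gid, res in disc.results.items():
        null = disc.nulls.get(gid)
        rows.append(
            {
                "gene_id": gid, "top_snp": res.top_snp, "min_p": res.min_p,
                "perm_threshold": null.threshold if null else np.nan,
                "empirical_p": null.empirical_p if null else np.nan,
                "log_or": res.log_or, "se": res.se,
                "significant": gid in disc.significant_genes,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "binary_scan.tsv", sep="\t", index=False)
    report["scan_binary"] = {
        "n_tested": disc.fdr.n_traits_tested,
        "n_significant": disc.fdr.n_significant,
        "fdr": disc.fdr.to_dict(),
    }


def _stage_scan_lmm(config, state, report, outdir):
    _require(state, "presence", "scan-lmm", "select")
    e = state["expression"]
    g = state["genotypes"]
    opts = dict(config.scan_lmm)
    frac = opts.pop("presence_frac")
    counts = state["presence"].presence_counts()
    wide = [gid for gid in e.gene_ids if counts[gid] > frac * e.n_accessions]
    if not wide:
        raise RuntimeError("no widely expressed genes for the quantitative scan")
    disc = lmm.standard_discover(
        e, g, wide, seed=stage_seed(config.seed, "scan-lmm"), **opts
    )
    state["lmm_discovery"] = disc
    rows = [
        {
            "gene_id": gid, "top_snp": disc.scans[gid].top_snp,
            "min_p": disc.scans[gid].min_p, "h2": disc.fits[gid].h2,
            "significant": gid in disc.significant_genes,
        }
        for gid in wide
    ]
    pd.DataFrame(rows).to_csv(outdir / "lmm_scan.tsv", sep="\t", index=False)
    report["scan_lmm"] = {
        "n_tested": disc.fdr.n_traits_tested,
        "n_significant": disc.fdr.n_significant,
        "threshold_neglog10": disc.threshold.threshold_neglog10,
        "fdr": disc.fdr.to_dict(),
    }


def _stage_peaks(config, state, report, outdir):
    _require(state, "lmm_discovery", "peaks", "scan-lmm")
    ds = state["dataset"]
    g = state["genotypes"]
    disc = state["lmm_discovery"]
    all_peaks = []
    for gid in disc.significant_genes:
        for pk in peaks_mod.define_peaks(
            disc.scans[gid], g, disc.threshold.threshold_p
        ):
            all_peaks.append(peaks_mod.classify(pk, ds.annotation))
    state["peaks"] = all_peaks
    peaks_mod.peak_table(all_peaks).to_csv(outdir / "peaks.tsv", sep="\t", index=False)
    n_cis = sum(1 for p in all_peaks if p.classification == "cis")
    report["peaks"] = {
        "n_peaks": len(all_peaks),
        "n_cis": n_cis,
        "n_trans": len(all_peaks) - n_cis,
    }


def _stage_replicate(config, state, report, outdir):
    _require(state, "binary_discovery", "replicate", "scan-binary")
    ds = state["dataset"]
    if not ds.truth.records:
        log.info("[replicate] no synthetic truth; skipping panel simulation")
        return
    sc = state.get("sim_config") or SimConfig()
    seed2 = stage_seed(config.seed, "replicate")
    ds2 = simulate_replication_dataset(sc, ds.truth, seed2)
    b2 = binarize(ds2.expression)
    g1 = state["genotypes"]
    alpha = config.replicate["alpha"]
    sign_rule = config.replicate["sign_rule"]

    rows = []
    n_rep = 0
    tested = 0
    disc = state["binary_discovery"]
    for gid in disc.significant_genes:
        res = disc.results[gid]
        snp = res.top_index
        pk = peaks_mod.EqtlPeak(gid, res.top_snp, str(g1.chrom[snp]), int(g1.pos[snp]), res.min_p)
        y2 = b2.gene_vector(gid).astype(float)
        pheno = y2 if 0 < y2.sum() < len(y2) else None
        rr = replication.replicate(
            pk, pheno, ds2.genotypes, "binary",
            discovery_result=res, genotypes1=g1, alpha=alpha, sign_rule=sign_rule,
        )
        if rr.reason != "not_expressed":
            tested += 1
            n_rep += rr.replicated
        rows.append(
            {
                "gene_id": gid, "best_p": rr.best_p, "threshold": rr.region_threshold,
                "n_region_snps": rr.n_region_snps, "sign_consistent": rr.sign_consistent,
                "replicated": rr.replicated, "reason": rr.reason,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "replication.tsv", sep="\t", index=False)
    fdr = replication.replication_fdr(tested, n_rep, alpha) if tested else None
    report["replicate"] = {
        "n_tested": tested,
        "n_replicated": n_rep,
        "fdr": fdr.to_dict() if fdr else None,
    }


def _stage_covcor(config, state, report, outdir):
    _require(state, "selection", "covcor", "select")
    b = state["presence"]
    g = state["genotypes"]
    counts = b.presence_counts()
    n = len(b.accession_ids)
    usable = [
        gid for gid in state["selection"].selected_gene_ids if 0 < counts[gid] < n
    ]
    if len(usable) < 2:
        # fall back to every variably detected gene on small panels
        usable = [gid for gid in b.gene_ids if 0 < counts[gid] < n]
        log.info("[covcor] fewer than 2 selected genes; using all %d variable genes",
                 len(usable))
    if len(usable) < 2:
        raise RuntimeError("too few variable genes for the relationship matrix")
    br = covcor.binary_relationship(b, usable)
    grm = lmm.grm_freq(g, regularization=0.0)
    mc = covcor.correlate_matrices(
        br, grm, mantel_perms=config.covcor["mantel_perms"],
        seed=stage_seed(config.seed, "covcor"),
    )
    state["covcor"] = mc
    excess = covcor.expected_excess_shared(len(usable), mc.r)
    report["covcor"] = dict(mc.to_dict(), n_genes=len(usable), expected_excess_shared=excess)
    with open(outdir / "covcor.json", "w") as fh:
        json.dump(report["covcor"], fh, indent=1)


def _stage_sv(config, state, report, outdir):
    _require(state, "presence", "sv", "select")
    ds = state["dataset"]
    calls = sv_mod.call_svs(
        ds.masks, ds.annotation, min_carriers=config.sv["min_carriers"]
    )
    assoc = sv_mod.associate_all(calls, state["presence"], alpha=config.sv["alpha"])
    summary = sv_mod.sv_summary(calls, assoc)
    state["sv_calls"] = calls
    pd.DataFrame(
        [
            {"gene_id": a.gene_id, "sv_type": a.sv_type, "fisher_p": a.fisher_p,
             "odds_ratio": a.odds_ratio,
             "significant_nominal": a.significant_nominal,
             "significant_bonferroni": a.significant_bonferroni}
            for a in assoc
        ]
    ).to_csv(outdir / "sv_associations.tsv", sep="\t", index=False)
    report["sv"] = {
        k: v for k, v in summary.items()
        if k not in ("per_accession_counts", "per_gene_carrier_counts")
    }


def _stage_report(config, state, report, outdir):
    ds = state.get("dataset")
    if ds is not None and ds.truth.records:
        planted_binary = {
            r["gene_id"]
            for r in ds.truth.records
            if r["effect_type"] in ("presence", "sv_deletion")
        }
        planted_add = {
            r["gene_id"] for r in ds.truth.records if r["effect_type"] == "additive"
        }
        truth_block = {}
        if "binary_discovery" in state:
            hits = set(state["binary_discovery"].significant_genes)
            scanned = set(state["binary_discovery"].results)
            reachable = planted_binary & scanned
            truth_block["binary_recall"] = (
                len(hits & reachable) / len(reachable) if reachable else None
            )
            truth_block["binary_false_hits"] = len(hits - planted_binary)
        if "lmm_discovery" in state:
            hits = set(state["lmm_discovery"].significant_genes)
            scanned = set(state["lmm_discovery"].scans)
            reachable = planted_add & scanned
            truth_block["lmm_recall"] = (
                len(hits & reachable) / len(reachable) if reachable else None
            )
        report["truth_eval"] = truth_block
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "select": _stage_select,
    "scan-binary": _stage_scan_binary,
    "scan-lmm": _stage_scan_lmm,
    "peaks": _stage_peaks,
    "replicate": _stage_replicate,
    "covcor": _stage_covcor,
    "sv": _stage_sv,
    "report": _stage_report,
}
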