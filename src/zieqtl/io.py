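"""Readers, writers and QC filters for the standard input formats.

Supported on disk: VCF (GT fields only, via cyvcf2), a plain-text genotype
TSV dialect, expression TSV, GFF3 gene annotation, BED coverage masks.
Internally every coordinate is 1-based inclusive; BED's 0-based half-open
convention is converted at this boundary.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BinaryPresenceMatrix,
    CoverageMask,
    EmptyResultError,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    ValidationError,
)

log = logging.getLogger("zieqtl")


class ParseError(ValueError):
    pass


def _snp_id_to_map(snp_ids: Sequence[str]):
    """TSV dialect SNP ids are '<chrom>_<pos>'."""
    chrom, pos = [], []
    for sid in snp_ids:
        c, _, p = str(sid).rpartition("_")
        if not c or not p.isdigit():
            raise ParseError(f"snp id {sid!r} is not of the form <chrom>_<pos>")
        chrom.append(c)
        pos.append(int(p))
    return np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64)


def _orient_to_minor(dosage: np.ndarray) -> np.ndarray:
    """Flip columns so dosage counts the sample minor allele."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dosage, axis=0) / 2.0
    flip = f > 0.5
    out = dosage.copy()
    out[:, flip] = 2.0 - out[:, flip]
    return out


def load_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from VCF or the plain-text TSV dialect.

    Dosages are re-oriented to count the minor allele determined from the
    sample frequency. Sites with more than two alleles are skipped with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _load_vcf(path)
    if format == "tsv":
        return _load_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accession_ids = list(vcf.samples)
    snp_ids, chrom, pos, cols = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            log.warning(
                "skipping site %s:%d with alleles %s",
                variant.CHROM,
                variant.POS,
                [variant.REF] + list(variant.ALT),
            )
            continue
        gt = np.asarray(variant.gt_types, dtype=float)  # 0,1,2; 3=missing
        gt[gt == 3] = np.nan
        snp_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        cols.append(gt)
    if not cols:
        raise EmptyResultError(f"no biallelic sites in {path}")
    dosage = _orient_to_minor(np.column_stack(cols))
    return GenotypeMatrix(accession_ids, snp_ids, chrom, pos, dosage)


def _load_genotype_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse genotype TSV {path}: {exc}") from exc
    snp_ids = [str(c) for c in df.columns]
    chrom, pos = _snp_id_to_map(snp_ids)
    raw = df.replace({"NA": np.nan, "": np.nan}).to_numpy(dtype=float)
    bad = ~(np.isnan(raw) | np.isin(raw, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"invalid dosage {raw[i, j]!r} at accession {df.index[i]!r}, "
            f"snp {snp_ids[j]!r} (line {i + 2})"
        )
    order = np.lexsort((pos, chrom.astype(str)))
    dosage = _orient_to_minor(raw[:, order])
    return GenotypeMatrix(
        list(df.index), [snp_ids[i] for i in order], chrom[order], pos[order], dosage
    )


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    arr = g.dosage.astype(object)
    df = pd.DataFrame(arr, index=g.accession_ids, columns=g.snp_ids)
    df.index.name = "accession"
    with np.errstate(invalid="ignore"):
        df = df.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t")


def filter_genotypes(
    g: GenotypeMatrix, maf_min: float = 0.05, callrate_min: float = 0.95
) -> GenotypeMatrix:
    """Keep SNPs with MAF strictly above `maf_min` and call rate >= `callrate_min`."""
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < callrate_min <= 1):
        raise ValueError("callrate_min must be in (0, 1]")
    keep = (g.compute_maf() > maf_min) & (g.call_rate() >= callrate_min)
    if not keep.any():
        raise EmptyResultError("all SNPs removed by QC filter")
    return g.take_snps(np.flatnonzero(keep))


def filter_accessions_by_transcript_callrate(
    e: ExpressionMatrix, mode: str = "robust", *, drop: Sequence[str] = (), k: float = 4.0
) -> ExpressionMatrix:
    """Drop accessions with anomalously few detected transcripts.

    mode='list' drops the named accessions. mode='robust' drops accessions
    whose count of genes with value > 0 falls below median - k * MAD of the
    per-accession counts; MAD = 0 degenerates to dropping nothing.
    """
    if mode == "list":
        if not drop:
            return e
        return e.drop_accessions(list(drop))
    if mode != "robust":
        raise ValueError(f"unknown mode {mode!r}")
    counts = (e.values > 0).sum(axis=1).astype(float)
    med = np.median(counts)
    mad = np.median(np.abs(counts - med))
    if mad == 0:
        return e
    cutoff = med - k * mad
    keep = [a for a, c in zip(e.accession_ids, counts) if c >= cutoff]
    dropped = [a for a, c in zip(e.accession_ids, counts) if c < cutoff]
    if dropped:
        log.info("dropping accessions with low transcript call rate: %s", dropped)
    return e.take_accessions(keep)


def load_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"negative expression value in {path}")
    return ExpressionMatrix(list(df.index), [str(c) for c in df.columns], values)


def write_expression_tsv(e: ExpressionMatrix, path) -> None:
    df = e.to_frame()
    df.index.name = "accession"
    df.to_csv(path, sep="\t", float_format="%.17g")


# -- annotation -------------------------------------------------------------

def load_annotation(path, format: str | None = None) -> GeneAnnotation:
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix == ".bed" else "gff3"
    if format == "gff3":
        return _load_gff3(path)
    if format == "bed":
        return _load_annotation_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _load_gff3(path: Path) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for f in db.features_of_type("gene"):
        gene_id = f.attributes.get("ID", [f.id])[0]
        rows.append((gene_id, f.seqid, f.start, f.end, f.strand))
    if not rows:
        raise EmptyResultError(f"no gene features in {path}")
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    return GeneAnnotation(df)


def _load_annotation_bed(path: Path) -> GeneAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(df.set_index("gene_id")[["chrom", "start", "end", "strand"]])


def write_annotation_gff3(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, row in ann.df.iterrows():
            fh.write(
                f"{row.chrom}\tzieqtl\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={gene_id}\n"
            )


# -- coverage masks ---------------------------------------------------------

def _read_mask_bed(path, accession_id: str) -> CoverageMask:
    tuples = []
    with open(path) as fh:
        last = {}
        warned = False
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path} line {ln}: expected >=3 BED columns")
            c, s, e = parts[0], int(parts[1]), int(parts[2])
            if c in last and s < last[c] and not warned:
                log.warning("unsorted BED %s; sorting", path)
                warned = True
            last[c] = s
            tuples.append((c, s + 1, e))  # BED half-open -> 1-based inclusive
    return CoverageMask.from_tuples(accession_id, tuples)


def load_coverage_masks(dir_or_manifest) -> list[CoverageMask]:
    """Load one BED file per accession from a directory or a manifest TSV.

    A directory is expected to contain ``<accession>.bed`` files; a manifest
    is a two-column TSV of accession id and BED path.
    """
    p = Path(dir_or_manifest)
    masks = []
    if p.is_dir():
        for bed in sorted(p.glob("*.bed")):
            masks.append(_read_mask_bed(bed, bed.stem))
    else:
        man = pd.read_csv(p, sep="\t", header=None, names=["accession", "path"])
        for _, row in man.iterrows():
            bed = Path(row["path"])
            if not bed.is_absolute():
                bed = p.parent / bed
            masks.append(_read_mask_bed(bed, str(row["accession"])))
    return masks


def write_mask_bed(mask: CoverageMask, path) -> None:
    with open(path, "w") as fh:
        for c, s, e in mask.to_tuples():
            fh.write(f"{c}\t{s - 1}\t{e}\n")  # back to 0-based half-open


def write_masks(masks: Sequence[CoverageMask], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in masks:
        write_mask_bed(m, outdir / f"{m.accession_id}.bed")


def write_presence_tsv(b: BinaryPresenceMatrix, path) -> None:
    df = pd.DataFrame(b.present, index=b.accession_ids, columns=b.gene_ids)
    df.index.name = "accession"
    df.to_csv(path, sep="\t")
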