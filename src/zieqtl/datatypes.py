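"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 1-based inclusive (GFF3/TAIR-style); BED input is
converted at the IO boundary. Dosages count copies of the minor allele and are
stored as floats with ``nan`` marking missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


class EmptyResultError(ValueError):
    """Raised when a filter removes every row/column."""


def _as_str_list(x: Iterable) -> list[str]:
    return [str(v) for v in x]


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with per-SNP map information.

    Attributes
    ----------
    accession_ids : list of str
    snp_ids : list of str
        Unique SNP identifiers; the plain-text dialect uses ``<chrom>_<pos>``.
    chrom, pos : ndarray
        Per-SNP chromosome label and 1-based position, strictly increasing
        within each chromosome.
    dosage : ndarray, shape (n_accessions, n_snps)
        Minor-allele counts in {0, 1, 2}; ``nan`` marks missing calls.
    maf : ndarray
        Minor-allele frequency per SNP, recomputed from non-missing dosages.
    """

    accession_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    maf: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.accession_ids = _as_str_list(self.accession_ids)
        self.snp_ids = _as_str_list(self.snp_ids)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.accession_ids) or m != len(self.snp_ids):
            raise ValidationError("dosage shape does not match id lists")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicated snp_ids")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(f"positions not strictly increasing on {c}")
        if self.maf is None:
            self.maf = self.compute_maf()
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    # -- derived quantities -------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def compute_maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    # -- subsetting ---------------------------------------------------------
    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.accession_ids,
            [self.snp_ids[i] for i in idx],
            self.chrom[idx],
            self.pos[idx],
            self.dosage[:, idx],
            self.maf[idx],
        )

    def take_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise ValidationError(f"unknown accession ids: {missing}")
        rows = [lookup[a] for a in ids]
        g = GenotypeMatrix(
            list(ids), self.snp_ids, self.chrom, self.pos, self.dosage[rows, :]
        )
        return g

    def window_index(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Indices of SNPs on `chrom` with lo <= pos <= hi."""
        on = np.flatnonzero(self.chrom == chrom)
        p = self.pos[on]
        i0 = np.searchsorted(p, lo, side="left")
        i1 = np.searchsorted(p, hi, side="right")
        return on[i0:i1]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(snp_id) from None


@dataclass
class ExpressionMatrix:
    """Accessions x genes matrix of non-negative normalized abundances."""

    accession_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = _as_str_list(self.accession_ids)
        self.gene_ids = _as_str_list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.accession_ids) or m != len(self.gene_ids):
            raise ValidationError("values shape does not match id lists")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicated gene_ids")
        if np.any(self.values < 0):
            raise ValidationError("negative expression value")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.accession_ids, columns=self.gene_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]

    def take_accessions(self, ids: Sequence[str]) -> "ExpressionMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise ValidationError(f"unknown accession ids: {missing}")
        rows = [lookup[a] for a in ids]
        return ExpressionMatrix(list(ids), self.gene_ids, self.values[rows, :])

    def drop_accessions(self, ids: Sequence[str]) -> "ExpressionMatrix":
        lookup = set(self.accession_ids)
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise ValidationError(f"unknown accession ids: {missing}")
        keep = [a for a in self.accession_ids if a not in set(ids)]
        return self.take_accessions(keep)


@dataclass
class BinaryPresenceMatrix:
    """0/1 companion of an ExpressionMatrix: 1 exactly where value > 0."""

    accession_ids: list[str]
    gene_ids: list[str]
    present: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = _as_str_list(self.accession_ids)
        self.gene_ids = _as_str_list(self.gene_ids)
        self.present = np.asarray(self.present, dtype=np.int8)
        if not np.isin(self.present, (0, 1)).all():
            raise ValidationError("presence values must be 0/1")

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return self.present[:, self.gene_ids.index(gene_id)]

    def presence_counts(self) -> pd.Series:
        return pd.Series(self.present.sum(axis=0), index=self.gene_ids)


@dataclass
class GeneAnnotation:
    """Gene coordinates; ``tss`` is start on '+' strand and end on '-'."""

    df: pd.DataFrame  # index gene_id; columns chrom, start, end, strand, tss

    REQUIRED = ("chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for c in self.REQUIRED:
            if c not in df.columns:
                raise ValidationError(f"annotation missing column {c}")
        if (df["start"] > df["end"]).any():
            raise ValidationError("gene with start > end")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        if "tss" not in df.columns:
            df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
        if df.index.duplicated().any():
            raise ValidationError("duplicated gene ids in annotation")
        self.df = df

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.df.index

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.df.index:
            raise KeyError(gene_id)
        return self.df.loc[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)


def normalize_intervals(intervals: Iterable[tuple[str, int, int]]):
    """Sort and merge 1-based inclusive intervals; abutting intervals merge."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        if s > e:
            raise ValidationError(f"interval with start > end: {(c, s, e)}")
        by_chrom.setdefault(str(c), []).append((int(s), int(e)))
    out: dict[str, np.ndarray] = {}
    for c, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[c] = np.asarray(merged, dtype=np.int64)
    return out


@dataclass
class CoverageMask:
    """Per-accession zero-coverage intervals, normalized per chromosome."""

    accession_id: str
    intervals: Mapping[str, np.ndarray]  # chrom -> (k, 2) start/end, merged

    @classmethod
    def from_tuples(cls, accession_id, tuples) -> "CoverageMask":
        return cls(str(accession_id), normalize_intervals(tuples))

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for c in sorted(self.intervals):
            for s, e in self.intervals[c]:
                out.append((c, int(s), int(e)))
        return out

    def covers_point(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        return i >= 0 and ivs[i, 1] >= pos

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end] lies within one merged zero-coverage run."""
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        i = np.searchsorted(ivs[:, 0], start, side="right") - 1
        return i >= 0 and ivs[i, 1] >= end
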