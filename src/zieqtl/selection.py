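"""Binarization, variable-gene selection and detection summaries.

A transcript is scored present when its normalized abundance is strictly
positive. Genes carried into the presence/absence scan are those detected
in an intermediate fraction of accessions (strictly between the bounds)
and expressed above a floor set by the always-detected genes, which
removes most genes whose zeros are plausibly detection dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BinaryPresenceMatrix, ExpressionMatrix


def binarize(e: ExpressionMatrix) -> BinaryPresenceMatrix:
    """1 exactly where the expression value is > 0."""
    return BinaryPresenceMatrix(
        e.accession_ids, e.gene_ids, (e.values > 0).astype(np.int8)
    )


@dataclass
class SelectionReport:
    selected_gene_ids: list[str]
    n_total: int
    presence_count: pd.Series
    level_threshold: float
    lower_bound: float = field(default=np.nan)
    upper_bound: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"presence_count": self.presence_count})
        df["selected"] = df.index.isin(self.selected_gene_ids)
        return df


def _detected_means(e: ExpressionMatrix) -> np.ndarray:
    """Mean over accessions where the gene is detected; nan if never."""
    v = e.values
    det = v > 0
    cnt = det.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, v.sum(axis=0) / cnt, np.nan)


def select_variable_genes(
    e: ExpressionMatrix,
    b: BinaryPresenceMatrix | None = None,
    lower_frac: float = 0.10,
    upper_frac: float = 0.90,
) -> SelectionReport:
    """Select genes detected in an intermediate share of accessions.

    A gene is selected iff (i) lower_frac*n < presence count < upper_frac*n
    (both strict) and (ii) its mean expression over the accessions where it
    is detected exceeds the mean of the 2nd-lowest-expressed gene among
    genes detected in every accession.
    """
    if b is None:
        b = binarize(e)
    n = e.n_accessions
    counts = b.present.sum(axis=0)
    means = _detected_means(e)
    always = counts == n
    if always.sum() < 2:
        raise ValueError(
            "need at least 2 genes detected in all accessions to set the "
            "expression-level floor"
        )
    level_threshold = float(np.sort(means[always])[1])
    lo, hi = lower_frac * n, upper_frac * n
    sel = (counts > lo) & (counts < hi) & (means > level_threshold)
    selected = [g for g, s in zip(e.gene_ids, sel) if s]
    return SelectionReport(
        selected,
        len(e.gene_ids),
        pd.Series(counts, index=e.gene_ids),
        level_threshold,
        lo,
        hi,
    )


def _status(counts: pd.Series, n: int) -> pd.Series:
    out = pd.Series("variable", index=counts.index)
    out[counts == n] = "core"
    out[counts == 0] = "absent"
    return out


def overlap_summary(b1: BinaryPresenceMatrix, b2: BinaryPresenceMatrix) -> dict:
    """Cross-tabulate detection status of the union of genes in two panels.

    Status per panel: core (detected in all accessions), variable (some but
    not all), absent (none), missing (gene not scored in that panel). The
    returned counts partition the union of gene ids.
    """
    c1, c2 = b1.presence_counts(), b2.presence_counts()
    union = c1.index.union(c2.index)
    s1 = _status(c1, len(b1.accession_ids)).reindex(union, fill_value="missing")
    s2 = _status(c2, len(b2.accession_ids)).reindex(union, fill_value="missing")
    tab = pd.crosstab(s1, s2)
    counts = {
        f"{a}_{b}": int(tab.loc[a, b]) if a in tab.index and b in tab.columns else 0
        for a in ("core", "variable", "absent", "missing")
        for b in ("core", "variable", "absent", "missing")
    }
    counts["n_union"] = len(union)
    return counts


def detection_summaries(e: ExpressionMatrix) -> dict:
    """Per-accession detected-gene counts and the level/detection trend.

    Ranks are computed on mean expression over the accessions where each
    gene is detected; the Spearman correlation between that rank and the
    number of accessions with detected transcripts quantifies the
    detection-dropout trend (positive when low-expressed genes drop out).
    """
    per_accession = pd.Series(
        (e.values > 0).sum(axis=1), index=e.accession_ids, name="n_genes_detected"
    )
    counts = (e.values > 0).sum(axis=0)
    means = _detected_means(e)
    detected = counts > 0
    per_gene = pd.DataFrame(
        {
            "detected_mean": means,
            "n_accessions_detected": counts,
        },
        index=e.gene_ids,
    )
    per_gene["level_rank"] = per_gene["detected_mean"].rank()
    if detected.sum() >= 3 and np.ptp(counts[detected]) > 0 and (
        np.nanstd(means[detected]) > 0
    ):
        rho, p = stats.spearmanr(means[detected], counts[detected])
    else:
        rho, p = np.nan, np.nan
    return {
        "per_accession": per_accession,
        "per_gene": per_gene,
        "spearman_rho": float(rho),
        "spearman_p": float(p) if np.isfinite(p) else np.nan,
    }
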