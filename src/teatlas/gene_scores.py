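"""Per-gene regulatory TE-density scoring and TE-regulated gene calling.

The regulatory TE density of a gene, in one cell line and one assay, is

    density = TE-derived regulatory bp / total regulatory bp

within the 10 Kb neighborhood centered on the gene's principal-transcript
TSS (5 Kb on either side).  Densities are computed against each cell line's
own peak set, not the merged atlas: the gene x cell-line matrix is the basis
for cross-cell-line correlation and for calling TE-regulated genes at
per-assay cutoffs (density >= 0.1 for DHS and HR, >= 0.3 for HA, boundary
inclusive).  A gene with no regulatory sequence in its neighborhood has an
*undefined* density — carried as missing, never as zero — and is excluded
from means, correlations and calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .formats import TERecord, TSSRecord
from .intervals import GenomeLayout, IntervalSet

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_FLANK_BP",
    "GeneRegulatoryProfile",
    "score_gene",
    "density_matrix",
    "cellline_correlation",
    "call_te_regulated",
    "sharing_spectrum",
    "correlation_linkage",
]

DEFAULT_FLANK_BP = 5000
DEFAULT_THRESHOLDS = {"DHS": 0.1, "HA": 0.3, "HR": 0.1}


@dataclass(frozen=True)
class GeneRegulatoryProfile:
    """TE density of one gene's neighborhood in one cell line and assay."""

    gene_id: str
    cellline: str
    assay: str
    reg_bp: int
    te_reg_bp: int

    @property
    def density(self) -> float | None:
        """te_reg_bp / reg_bp, or None when the gene has no regulatory bp."""
        if self.reg_bp == 0:
            return None
        return self.te_reg_bp / self.reg_bp


def score_gene(
    gene: TSSRecord,
    cellline_regions: IntervalSet,
    te_set: IntervalSet,
    cellline: str = "",
    assay: str = "",
    flank_bp: int = DEFAULT_FLANK_BP,
) -> GeneRegulatoryProfile:
    """Score one gene against one cell line's peak set.

    ``te_set`` is the normalized union of TE footprints (see
    :func:`teatlas.te_profile.te_union`).
    """
    layout = cellline_regions.layout
    lo = max(0, gene.position - flank_bp)
    hi = min(layout.length(gene.chrom), gene.position + flank_bp)
    window = IntervalSet.from_pairs(layout, [(gene.chrom, lo, hi)])
    reg = window.intersect(cellline_regions)
    te_reg = reg.intersect(te_set)
    return GeneRegulatoryProfile(
        gene_id=gene.gene_id,
        cellline=cellline,
        assay=assay,
        reg_bp=reg.total_bp,
        te_reg_bp=te_reg.total_bp,
    )


def density_matrix(
    genes: Sequence[TSSRecord],
    per_cellline_peaks: Mapping[str, IntervalSet],
    te_set: IntervalSet,
    assay: str = "",
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Gene x cell-line density matrix (NaN where density is undefined).

    Exactly reproduces per-gene :func:`score_gene` results but uses
    prefix-sum range queries: for each cell line the TE-covered regulatory
    set is intersected once, after which each gene window costs O(log n).
    """
    gene_ids = [g.gene_id for g in genes]
    data = np.full((len(genes), len(per_cellline_peaks)), np.nan)
    layout = te_set.layout
    by_chrom: dict[str, list[tuple[int, TSSRecord]]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append((i, g))
    for j, (cl, peaks) in enumerate(per_cellline_peaks.items()):
        te_reg_set = peaks.intersect(te_set)
        for chrom, items in by_chrom.items():
            idx = np.array([i for i, _ in items])
            pos = np.array([g.position for _, g in items], dtype=np.int64)
            lo = np.maximum(0, pos - flank_bp)
            hi = np.minimum(layout.length(chrom), pos + flank_bp)
            reg = peaks.overlap_bp_ranges(chrom, lo, hi)
            te_reg = te_reg_set.overlap_bp_ranges(chrom, lo, hi)
            with np.errstate(invalid="ignore"):
                dens = np.where(reg > 0, te_reg / np.maximum(reg, 1), np.nan)
            data[idx, j] = dens
    return pd.DataFrame(data, index=gene_ids, columns=list(per_cellline_peaks))


def cellline_correlation(
    matrix: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation between cell lines.

    For each cell-line pair only genes with a defined density in both are
    used; pairs with fewer than ``min_pairs`` complete observations get NaN.
    Returns ``(r_matrix, n_used)``, both cell line x cell line.
    """
    r = matrix.corr(method="pearson", min_periods=min_pairs)
    notna = matrix.notna().astype(int)
    n_used = pd.DataFrame(
        notna.T.values @ notna.values, index=matrix.columns, columns=matrix.columns
    )
    return r, n_used


def call_te_regulated(
    matrix: pd.DataFrame,
    assay: str,
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Call TE-regulated (gene, cell line) pairs at the assay's cutoff.

    Returns a long-format frame with columns ``gene_id, cellline, assay,
    density, called``; undefined densities are never called.
    """
    th = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if assay not in th:
        raise KeyError(f"no threshold for assay {assay!r}")
    cutoff = th[assay]
    if not (0 < cutoff <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {cutoff}")
    long = matrix.stack(future_stack=True).rename("density").reset_index()
    long.columns = ["gene_id", "cellline", "density"]
    long["assay"] = assay
    long["called"] = long["density"].ge(cutoff).fillna(False)
    return long[["gene_id", "cellline", "assay", "density", "called"]]


def sharing_spectrum(calls: pd.DataFrame, n_celllines: int | None = None) -> dict[int, int]:
    """Number of genes called in exactly k cell lines, k = 1..N.

    ``calls`` is the frame from :func:`call_te_regulated` (one assay).  The
    counts over k sum to the number of distinct called genes.
    """
    called = calls[calls["called"]]
    n = n_celllines or calls["cellline"].nunique()
    spectrum = {k: 0 for k in range(1, n + 1)}
    if len(called):
        per_gene = called.groupby("gene_id")["cellline"].nunique()
        for k, cnt in per_gene.value_counts().items():
            spectrum[int(k)] = int(cnt)
    return spectrum


def correlation_linkage(r_matrix: pd.DataFrame) -> np.ndarray:
    """Average-linkage clustering of cell lines on distance 1 - r.

    Thin convenience utility; rendering a dendrogram is left to the caller.
    """
    d = 1.0 - r_matrix.values
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")
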