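"""Tissue-specific-gene (TSG) analyses.

Two questions are asked of a TSG catalog against the per-assay density
matrix: (1) do a tissue's TSGs use more TE-derived regulatory sequence in
their own tissue's cell line(s) than elsewhere (mean-density contrast and
TE-regulated-fraction contrast), and (2) which TSGs carry TE-derived
regulatory sites *exclusively* in their own tissue — density >= 0.1 there
and exactly 0 in every other tissue's cell line.

For tissues mapped to several cell lines, "density in the respective
tissue" defaults to the maximum over that tissue's cell lines (switchable
to the mean or an all-lines requirement), and an undefined density in
another tissue's cell line counts as satisfying "0 in all other tissues"
(no TE-derived regulatory sequence exists there; a strict mode requires a
defined 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import TSGCatalog
from .te_profile import TTestResult, compare_mean_divergence

__all__ = ["TSGContrast", "TissueExclusiveCall", "tsg_contrast", "tissue_exclusive_genes"]


@dataclass(frozen=True)
class TSGContrast:
    """Own-vs-other contrast of a tissue's TSGs for one assay."""

    tissue: str
    assay: str
    mean_density_own: float
    mean_density_other: float
    t_stat: float
    p_value: float
    n_own: int
    n_other: int
    fraction_called_own: float
    fraction_called_other: float

    @property
    def complete(self) -> bool:
        """False when either group had no defined densities."""
        return self.n_own > 0 and self.n_other > 0


@dataclass(frozen=True)
class TissueExclusiveCall:
    """A TSG with TE-derived regulatory sites only in its own tissue."""

    tissue: str
    assay: str
    gene_id: str
    own_density: float
    max_other_density: float


def _split_columns(catalog: TSGCatalog, columns, tissue: str):
    own = [c for c in columns if catalog.cellline_to_tissue.get(c) == tissue]
    other = [c for c in columns if catalog.cellline_to_tissue.get(c) not in (None, tissue)]
    if not own:
        raise ValueError(f"tissue {tissue!r} has no mapped cell line in the matrix")
    return own, other


def tsg_contrast(
    catalog: TSGCatalog,
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    tissue: str,
    assay: str,
    equal_var: bool = False,
) -> TSGContrast:
    """Compare TSG regulatory TE density in the own tissue vs all others.

    Each defined (gene, cell line) density is one observation; the two
    groups are compared with a two-tailed t-test (Welch by default).
    Called fractions are the share of defined observations at or above the
    assay's cutoff, taken from ``calls`` (see
    :func:`teatlas.gene_scores.call_te_regulated`).
    """
    genes = sorted(catalog.tissue_to_genes.get(tissue, set()))
    if not genes:
        raise ValueError(f"tissue {tissue!r} has no TSGs in the catalog")
    own_cols, other_cols = _split_columns(catalog, matrix.columns, tissue)
    present = [g for g in genes if g in matrix.index]
    sub = matrix.loc[present]
    own_vals = sub[own_cols].values.ravel()
    other_vals = sub[other_cols].values.ravel()
    own_vals = own_vals[~np.isnan(own_vals)]
    other_vals = other_vals[~np.isnan(other_vals)]
    tt: TTestResult = compare_mean_divergence(own_vals, other_vals, equal_var=equal_var)

    c = calls[calls["gene_id"].isin(present)]
    own_calls = c[c["cellline"].isin(own_cols) & c["density"].notna()]
    other_calls = c[c["cellline"].isin(other_cols) & c["density"].notna()]
    return TSGContrast(
        tissue=tissue,
        assay=assay,
        mean_density_own=float(own_vals.mean()) if own_vals.size else float("nan"),
        mean_density_other=float(other_vals.mean()) if other_vals.size else float("nan"),
        t_stat=tt.t_stat,
        p_value=tt.p_value,
        n_own=int(own_vals.size),
        n_other=int(other_vals.size),
        fraction_called_own=(
            float(own_calls["called"].mean()) if len(own_calls) else float("nan")
        ),
        fraction_called_other=(
            float(other_calls["called"].mean()) if len(other_calls) else float("nan")
        ),
    )


def tissue_exclusive_genes(
    catalog: TSGCatalog,
    matrix: pd.DataFrame,
    tissue: str,
    assay: str,
    threshold: float = 0.1,
    own_agg: str = "max",
    undefined_counts_as_zero: bool = True,
) -> list[TissueExclusiveCall]:
    """TSGs with TE-derived regulatory sites only in the given tissue.

    A gene is listed iff its density in the tissue's own cell line(s)
    (aggregated by ``own_agg``: max, mean, or ``all`` = every line must
    pass) reaches ``threshold`` and its density is exactly 0 in every other
    tissue's cell line where defined.  With
    ``undefined_counts_as_zero=False`` an undefined density elsewhere
    disqualifies the gene instead of counting as absence.
    """
    if tissue not in catalog.tissue_to_genes:
        raise ValueError(f"tissue {tissue!r} absent from the TSG catalog")
    own_cols, other_cols = _split_columns(catalog, matrix.columns, tissue)
    out: list[TissueExclusiveCall] = []
    for gene in sorted(catalog.tissue_to_genes[tissue]):
        if gene not in matrix.index:
            continue
        own = matrix.loc[gene, own_cols].astype(float)
        other = matrix.loc[gene, other_cols].astype(float)
        own_def = own.dropna()
        if own_def.empty:
            continue
        if own_agg == "max":
            own_stat = float(own_def.max())
            passed = own_stat >= threshold
        elif own_agg == "mean":
            own_stat = float(own_def.mean())
            passed = own_stat >= threshold
        elif own_agg == "all":
            own_stat = float(own_def.min())
            passed = len(own_def) == len(own) and own_stat >= threshold
        else:
            raise ValueError(f"unknown own_agg {own_agg!r}")
        if not passed:
            continue
        other_def = other.dropna()
        if not undefined_counts_as_zero and len(other_def) != len(other):
            continue
        if (other_def != 0).any():
            continue
        out.append(
            TissueExclusiveCall(
                tissue=tissue,
                assay=assay,
                gene_id=gene,
                own_density=own_stat,
                max_other_density=float(other_def.max()) if len(other_def) else 0.0,
            )
        )
    return out
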