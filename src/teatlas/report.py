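"""Report layer: derived ratios and composition-table sheets.

These helpers turn raw bp/count totals into the derived quantities a
composition table prints — average region length, TE percentage,
shared/cell-line-specific fractions, gene-neighboring proportions and
relative TE-class percentages — at a fixed printed precision: one decimal
for percentages of totals, whole integers for average lengths and relative
class percentages.  Because they operate on plain totals they serve both
the pipeline's own summaries and any externally supplied table rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .atlas import AtlasSummary
from .formats import TE_CLASSES
from .te_profile import TECompositionTable

__all__ = [
    "average_length",
    "pct",
    "relative_class_pct",
    "composition_row",
    "composition_sheet",
    "summary_sheet",
]


def average_length(total_bp: int, region_count: int) -> int:
    """Average region length in bp, rounded to the nearest integer."""
    if region_count <= 0:
        raise ValueError("region_count must be positive")
    return int(round(total_bp / region_count))


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage at the stated printed precision (default one decimal)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def relative_class_pct(class_bp: int, te_bp: int) -> int:
    """Class share of total TE bp as a whole-number percentage."""
    if te_bp == 0:
        raise ValueError("zero TE bp")
    return int(round(100.0 * class_bp / te_bp))


def composition_row(
    label: str,
    total_bp: int,
    region_count: int,
    te_bp: int,
    class_bp: Mapping[str, int] | None = None,
) -> dict:
    """Derived quantities for one composition-table row of printed totals."""
    row = {
        "category": label,
        "total_bp": total_bp,
        "region_count": region_count,
        "average_length_bp": average_length(total_bp, region_count),
        "te_bp": te_bp,
        "te_pct": pct(te_bp, total_bp),
    }
    if class_bp:
        for c, bp in class_bp.items():
            row[f"{c}_bp"] = bp
            row[f"{c}_rel_pct"] = relative_class_pct(bp, te_bp)
    return row


def composition_sheet(
    comps: Mapping[str, TECompositionTable],
) -> pd.DataFrame:
    """Composition-table sheet from computed TE composition tables."""
    rows = []
    for label, comp in comps.items():
        if comp.total_regulatory_bp == 0:
            continue
        row = composition_row(
            label,
            comp.total_regulatory_bp,
            1 if comp.te_fragment_count == 0 else comp.te_fragment_count,
            comp.te_bp,
        )
        # region_count in a composition sheet is the fragment count column
        row["region_count"] = comp.te_fragment_count
        row.pop("average_length_bp", None)
        for c in TE_CLASSES:
            row[f"{c}_bp"] = comp.class_bp[c]
            if comp.te_bp:
                row[f"{c}_rel_pct"] = relative_class_pct(comp.class_bp[c], comp.te_bp)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_sheet(summary: AtlasSummary) -> pd.DataFrame:
    """Region-accounting sheet (bp, counts, average lengths, derived ratios)."""
    t = summary.table.reset_index()
    t["average_length_bp"] = [
        average_length(bp, n) if n else float("nan")
        for bp, n in zip(t["total_bp"], t["region_count"])
    ]
    overall_gw = summary.cell("overall", "genome_wide")["total_bp"]
    t["pct_of_overall"] = [
        pct(bp, overall_gw) if overall_gw else float("nan") for bp in t["total_bp"]
    ]
    t.insert(0, "assay", summary.assay)
    return t
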